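"""Seeded two-period expression simulator with latent-factor structure.

Expression arises from a sparse linear factor model: a genes x factors
loading matrix L (nonzero entries standard normal, density
``loading_density``), per-sample factor activities (standard normal), and
i.i.d. Gaussian noise.  Between period 1 and period 2 a subset of factors
shifts its activity mean by ``effect_size`` (in factor-sd units); genes with
any nonzero loading on a shifted factor are the planted "disease" genes
(label 1).  This emulates the premise that expression is driven by latent
regulatory factors, a few of which change as disease progresses, while
making no attempt at count-level realism — the downstream model consumes
standardized real values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import ExpressionMatrix, GeneLabelSet

__all__ = ["SyntheticSpec", "LabeledDataset", "generate",
           "default_benchmark_suite", "benchmark_protocol"]


@dataclass
class SyntheticSpec:
    """Parameters of one simulated two-period dataset."""

    n_genes: int = 500
    n_samples_per_period: int = 8
    n_factors: int = 20
    n_shifted_factors: int = 3
    loading_density: float = 0.02
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_shifted_factors > self.n_factors:
            raise ValueError(
                "n_shifted_factors cannot exceed n_factors "
                f"({self.n_shifted_factors} > {self.n_factors})"
            )
        if not (0.0 < self.loading_density <= 1.0):
            raise ValueError("loading_density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LabeledDataset:
    """Two period matrices over a shared gene set, plus planted labels."""

    period1: ExpressionMatrix
    period2: ExpressionMatrix
    labels: GeneLabelSet
    spec: SyntheticSpec | None = None


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw one dataset: loadings, per-period activities (shifted factors
    get mean +effect_size in period 2), expression = L @ activities + noise.
    Fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    G, F = spec.n_genes, spec.n_factors
    n = spec.n_samples_per_period
    mask = rng.random((G, F)) < spec.loading_density
    L = np.where(mask, rng.normal(size=(G, F)), 0.0)
    shifted = np.arange(spec.n_shifted_factors)  # first factors shift

    def _period(shift: bool):
        A = rng.normal(size=(F, n))
        if shift:
            A[shifted] += spec.effect_size
        return L @ A + rng.normal(scale=spec.noise_sd, size=(G, n))

    X1 = _period(False)
    X2 = _period(True)
    gene_ids = [f"g{i:05d}" for i in range(G)]
    labels = (mask[:, shifted].any(axis=1)).astype(int)
    return LabeledDataset(
        ExpressionMatrix(gene_ids, [f"p1_s{j}" for j in range(n)], X1),
        ExpressionMatrix(gene_ids, [f"p2_s{j}" for j in range(n)], X2),
        GeneLabelSet(gene_ids, labels),
        spec,
    )


def default_benchmark_suite() -> list:
    """The fixed scenario set used throughout the package's tests.

    * ``easy`` — 500 genes, 8+8 samples, 20 factors of which 3 shift with
      effect size 2.0, noise sd 0.5: a clearly planted but small-sample
      recovery problem.
    * ``null`` — identical but effect size 0: no signal at all.
    * ``full-scale`` — 4433 genes, for feasibility runs with the default
      400/20 hidden-unit architecture.
    """
    easy = SyntheticSpec()
    return [
        (easy, "easy: planted 3-factor shift, effect 2.0"),
        (replace(easy, effect_size=0.0), "null: no factor shift"),
        (replace(easy, n_genes=4433), "full-scale: 4433 genes"),
    ]


def benchmark_protocol(spec: SyntheticSpec, seed: int = 0) -> dict:
    """Training protocol used for the benchmark scenarios.

    The architecture follows the one-tenth rule (first hidden layer ~ a
    tenth of the genes, capped at 400; second layer a fifth of the first,
    capped at 20, so that the layer-2 selection threshold stays meaningful
    at 8 samples per period).  The Gaussian layer trains with batch-mean
    CD-1 gradients at a small learning rate (0.02) — Gaussian-visible RBMs
    need far smaller steps than binary ones to keep weights and biases from
    running away — while the binary layer takes the standard rate 0.5.
    Returns a dict of keyword arguments for
    :func:`srbmrank.ranking.run_variant`.
    """
    from .rbm import TrainingConfig

    n_hidden1 = min(400, max(2, spec.n_genes // 10))
    n_hidden2 = min(20, max(2, n_hidden1 // 5))
    return {
        "cfg1": TrainingConfig(eta=0.02, epochs=50, seed=seed,
                               mean_gradient=True),
        "cfg2": TrainingConfig(eta=0.5, epochs=400, seed=seed + 1,
                               mean_gradient=True),
        "n_hidden1": n_hidden1,
        "n_hidden2": n_hidden2,
    }
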