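"""Greedy layer-wise stacking of a Gaussian-Bernoulli RBM and a Bernoulli
RBM, forward propagation, and hidden-unit activation statistics.

The bottom RBM compresses the genes x samples expression data into a first
hidden layer (400 units by default); its binary hidden representations then
serve as training data for the top Bernoulli RBM (20 units by default).  A
hidden unit counts as "activated" on a sample when its conditional
probability is at least 0.5 (ties activate — one documented rule instead of
platform-dependent rounding); the activation frequency of a unit over a
sample set is the number of samples activating it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .rbm import (
    BB,
    GB,
    RBMParameters,
    TrainingConfig,
    TrainingTrace,
    p_hidden_given_visible,
    sample_binary,
    train_rbm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SRBMModel",
    "ActivationProfile",
    "train_srbm",
    "propagate",
    "activation_frequencies",
    "diff_freq_count_table",
    "weight_heatmap_export",
]

DEFAULT_N_HIDDEN1 = 400
DEFAULT_N_HIDDEN2 = 20
DEFAULT_EPOCHS1 = 50
DEFAULT_EPOCHS2 = 400


@dataclass
class SRBMModel:
    """Two stacked RBMs with their training traces and configurations."""

    rbm1: RBMParameters
    rbm2: RBMParameters | None
    trace1: TrainingTrace
    trace2: TrainingTrace | None
    config1: TrainingConfig
    config2: TrainingConfig | None
    gene_ids: list | None = None

    def __post_init__(self):
        if self.rbm2 is not None and self.rbm1.n_hidden != self.rbm2.n_visible:
            raise ValueError(
                f"layer mismatch: rbm1 has {self.rbm1.n_hidden} hidden units "
                f"but rbm2 expects {self.rbm2.n_visible} visible units"
            )

    @property
    def n_visible(self) -> int:
        return self.rbm1.n_visible

    @property
    def n_hidden1(self) -> int:
        return self.rbm1.n_hidden

    @property
    def n_hidden2(self) -> int:
        return 0 if self.rbm2 is None else self.rbm2.n_hidden


@dataclass
class ActivationProfile:
    """Per-unit activation counts over a sample set, for both hidden
    layers."""

    layer1_freq: np.ndarray
    layer2_freq: np.ndarray
    n_samples: int
    period_id: str = ""

    def __post_init__(self):
        self.layer1_freq = np.asarray(self.layer1_freq, dtype=int)
        self.layer2_freq = np.asarray(self.layer2_freq, dtype=int)
        for freq in (self.layer1_freq, self.layer2_freq):
            if freq.size and ((freq < 0) | (freq > self.n_samples)).any():
                raise ValueError(
                    "activation frequencies must lie in [0, n_samples]"
                )


def _as_sample_matrix(data) -> np.ndarray:
    """Accept an ExpressionMatrix (genes x samples) or a samples x units
    array; return samples x units."""
    if isinstance(data, ExpressionMatrix):
        return data.values.T
    return np.atleast_2d(np.asarray(data, dtype=float))


def train_srbm(
    data,
    cfg1: TrainingConfig | None = None,
    cfg2: TrainingConfig | None = None,
    n_hidden1: int = DEFAULT_N_HIDDEN1,
    n_hidden2: int = DEFAULT_N_HIDDEN2,
) -> SRBMModel:
    """Train the stack greedily: fit the GB layer on the standardized
    expression samples, propagate every sample to its binary layer-1
    representation (threshold mode), then fit the BB layer on those
    representations.  Deterministic given the config seeds.
    """
    if isinstance(data, ExpressionMatrix) and not data.standardized:
        raise ValueError("train_srbm requires standardized data")
    gene_ids = data.gene_ids if isinstance(data, ExpressionMatrix) else None
    X = _as_sample_matrix(data)
    if cfg1 is None:
        cfg1 = TrainingConfig(epochs=DEFAULT_EPOCHS1)
    if cfg2 is None:
        cfg2 = TrainingConfig(epochs=DEFAULT_EPOCHS2, seed=cfg1.seed + 1)
    rbm1, trace1 = train_rbm(X, cfg1, GB, n_hidden1)
    hidden1 = (p_hidden_given_visible(rbm1, X) >= 0.5).astype(float)
    if hidden1.shape[0] > 1 and (hidden1 == hidden1[0]).all():
        warnings.warn(
            "degenerate layer: propagated layer-1 representations are "
            "identical across samples",
            stacklevel=2,
        )
    rbm2, trace2 = train_rbm(hidden1, cfg2, BB, n_hidden2)
    return SRBMModel(rbm1, rbm2, trace1, trace2, cfg1, cfg2, gene_ids)


def propagate(model: SRBMModel, sample, mode: str = "threshold",
              rng: np.random.Generator | None = None):
    """Forward-propagate one sample (or a samples x genes matrix) through
    both layers, returning binary (layer1, layer2) states.

    ``threshold`` mode activates a unit when its conditional probability is
    >= 0.5 (deterministic); ``sample`` mode draws Bernoulli states and
    requires an rng.
    """
    if mode not in ("threshold", "sample"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "sample" and rng is None:
        raise ValueError("sample mode requires an rng")
    sample = np.asarray(sample, dtype=float)
    if sample.shape[-1] != model.n_visible:
        raise ValueError(
            f"sample length {sample.shape[-1]} != model n_visible "
            f"{model.n_visible}"
        )
    p1 = p_hidden_given_visible(model.rbm1, sample)
    h1 = (p1 >= 0.5).astype(float) if mode == "threshold" \
        else sample_binary(p1, rng)
    if model.rbm2 is None:
        return h1, np.zeros(h1.shape[:-1] + (0,))
    p2 = p_hidden_given_visible(model.rbm2, h1)
    h2 = (p2 >= 0.5).astype(float) if mode == "threshold" \
        else sample_binary(p2, rng)
    return h1, h2


def activation_frequencies(model: SRBMModel, data, mode: str = "threshold",
                           rng: np.random.Generator | None = None,
                           period_id: str = "") -> ActivationProfile:
    """Count, per hidden unit, how many samples activate it."""
    if isinstance(data, ExpressionMatrix):
        if not data.standardized:
            raise ValueError("activation_frequencies requires standardized data")
        if model.gene_ids is not None and data.gene_ids != model.gene_ids:
            raise ValueError("gene order differs from the training data")
    X = _as_sample_matrix(data)
    h1, h2 = propagate(model, X, mode=mode, rng=rng)
    return ActivationProfile(
        h1.sum(axis=0).astype(int),
        h2.sum(axis=0).astype(int),
        n_samples=X.shape[0],
        period_id=period_id,
    )


def diff_freq_count_table(a: ActivationProfile,
                          b: ActivationProfile) -> pd.DataFrame:
    """Tabulate, for each absolute frequency difference d >= 0, how many
    units of each hidden layer satisfy |freq_a - freq_b| = d."""
    if a.n_samples != b.n_samples:
        raise ValueError("profiles cover different sample counts")
    d1 = np.abs(a.layer1_freq - b.layer1_freq)
    d2 = np.abs(a.layer2_freq - b.layer2_freq)
    max_d = int(max(d1.max(initial=0), d2.max(initial=0)))
    rows = []
    for d in range(max_d + 1):
        rows.append(
            {
                "diff_freq": d,
                "hidden_layer_1": int((d1 == d).sum()),
                "hidden_layer_2": int((d2 == d).sum()),
            }
        )
    return pd.DataFrame(rows)


def weight_heatmap_export(model: SRBMModel, layer: int, path) -> None:
    """Export a layer's weight matrix as a plain TSV for plotting (rows are
    the layer's hidden units)."""
    if layer == 1:
        W = model.rbm1.W
    elif layer == 2:
        if model.rbm2 is None:
            raise ValueError("model has no second layer")
        W = model.rbm2.W
    else:
        raise ValueError("layer must be 1 or 2")
    pd.DataFrame(W).to_csv(path, sep="\t", header=False, index=False)
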