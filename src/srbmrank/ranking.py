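"""Gene prioritization from trained stacked-RBM models.

The procedure has two steps.  Step 1 compares hidden-unit activation
frequencies between the two time periods and selects the differentially
activated units (|delta frequency| strictly larger than a per-layer
threshold); units outside the selection are forced to 0 everywhere.  Step 2
scores each gene by the energy of its "circuit" through the selected units,

    E_g = (v_g - b1_g)^2 / 2 - sum_j h1_j w1_jg v_g
          - sum_i b2_i v2_i - sum_ij h2_j w2_ji v2_i,

(the layer-1 hidden-bias term, identical for all genes, is omitted; the two
RBM2 terms are shared across genes within a sample and cancel in within-
sample comparisons but still vary across samples), and ranks genes by the
absolute difference of their mean energy between periods,

    C_g = | mean_{s in period 1} E_g^s - mean_{s in period 2} E_g^s |.

Four variants are provided: SRBM-II (differential-unit selection, the
default), SRBM-I (all units, weakest third of each unit's fan-out pruned),
and RBM-II / RBM-I which use only the first (Gaussian-Bernoulli) layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix, standardize
from .rbm import TrainingConfig
from .srbm import (
    ActivationProfile,
    SRBMModel,
    activation_frequencies,
    propagate,
    train_srbm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronSelection",
    "GeneEnergyTable",
    "VariantSpec",
    "VariantRun",
    "VARIANT_NAMES",
    "differential_activation",
    "select_neurons",
    "prune_weak_connections",
    "gene_energy",
    "energy_change",
    "rank_genes",
    "run_variant",
]

VARIANT_NAMES = ("RBM-I", "RBM-II", "SRBM-I", "SRBM-II")

DEFAULT_T1 = 1  # layer-1 selection threshold (|delta freq| strictly above)
DEFAULT_T2 = 5  # layer-2 selection threshold
DEFAULT_PRUNE_FRACTION = 1.0 / 3.0


@dataclass
class NeuronSelection:
    """Index sets of the differentially activated units in each hidden
    layer, with the thresholds that produced them."""

    layer1_selected: np.ndarray
    layer2_selected: np.ndarray
    layer1_threshold: int = DEFAULT_T1
    layer2_threshold: int = DEFAULT_T2

    def __post_init__(self):
        self.layer1_selected = np.asarray(self.layer1_selected, dtype=int)
        self.layer2_selected = np.asarray(self.layer2_selected, dtype=int)

    @classmethod
    def all_units(cls, n1: int, n2: int) -> "NeuronSelection":
        return cls(np.arange(n1), np.arange(n2), 0, 0)


@dataclass
class GeneEnergyTable:
    """Per-gene, per-sample energies for both periods, the cross-period
    change C_g, and the descending rank (rank[0] indexes the gene with the
    largest change)."""

    gene_ids: list
    E1: np.ndarray
    E2: np.ndarray
    C: np.ndarray
    rank: np.ndarray

    def ranked_gene_ids(self) -> list:
        return [self.gene_ids[i] for i in self.rank]

    def ranked_scores(self) -> np.ndarray:
        return self.C[self.rank]


@dataclass
class VariantSpec:
    """Which ranking variant to run, and its knobs.

    ``prune_fraction`` applies to the I-variants (weak-connection pruning);
    the selection thresholds apply to the II-variants.
    """

    name: str = "SRBM-II"
    prune_fraction: float = DEFAULT_PRUNE_FRACTION
    layer1_threshold: int = DEFAULT_T1
    layer2_threshold: int = DEFAULT_T2

    def __post_init__(self):
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"variant must be one of {VARIANT_NAMES}")
        if not (0.0 <= self.prune_fraction < 1.0):
            raise ValueError("prune_fraction must lie in [0, 1)")

    @property
    def uses_stack(self) -> bool:
        return self.name.startswith("SRBM")

    @property
    def uses_selection(self) -> bool:
        return self.name.endswith("II")


@dataclass
class VariantRun:
    """Full output of an end-to-end variant run, for diagnostics."""

    table: GeneEnergyTable
    spec: VariantSpec
    models: list
    profiles: list
    selection: NeuronSelection
    regime: str = "pooled"


def differential_activation(a: ActivationProfile, b: ActivationProfile):
    """Per-unit absolute activation-frequency difference, per layer."""
    if (a.layer1_freq.size != b.layer1_freq.size
            or a.layer2_freq.size != b.layer2_freq.size):
        raise ValueError("profiles have different layer sizes")
    if a.n_samples != b.n_samples:
        raise ValueError("profiles cover different sample counts")
    return (np.abs(a.layer1_freq - b.layer1_freq),
            np.abs(a.layer2_freq - b.layer2_freq))


def select_neurons(diff1, diff2, t1: int = DEFAULT_T1,
                   t2: int = DEFAULT_T2) -> NeuronSelection:
    """Select units whose |delta frequency| is strictly larger than the
    per-layer threshold.  Empty selections are allowed (with a warning)."""
    if t1 < 0 or t2 < 0:
        raise ValueError("thresholds must be >= 0")
    diff1 = np.asarray(diff1)
    diff2 = np.asarray(diff2)
    sel1 = np.flatnonzero(diff1 > t1)
    sel2 = np.flatnonzero(diff2 > t2)
    if sel1.size == 0 and diff1.size:
        warnings.warn("empty layer-1 selection", stacklevel=2)
    if sel2.size == 0 and diff2.size:
        warnings.warn("empty layer-2 selection", stacklevel=2)
    return NeuronSelection(sel1, sel2, t1, t2)


def _prune_matrix(W: np.ndarray, fraction: float) -> np.ndarray:
    """Zero, for each lower-layer unit (column of W), the floor(fraction x
    fan-out) outgoing connections of smallest |w|; ties broken by lower
    target index pruned first."""
    n_out = W.shape[0]
    n_prune = int(np.floor(fraction * n_out))
    if n_prune == 0:
        return W.copy()
    W = W.copy()
    # stable argsort on |w| prunes lower target indices first among ties
    order = np.argsort(np.abs(W), axis=0, kind="stable")
    cols = np.arange(W.shape[1])[None, :]
    W[order[:n_prune], cols] = 0.0
    return W


def prune_weak_connections(model, fraction: float = DEFAULT_PRUNE_FRACTION):
    """Return a copy with each unit's weakest outgoing connections zeroed.

    Accepts an :class:`SRBMModel` (prunes both weight matrices) or a bare
    :class:`~srbmrank.rbm.RBMParameters`.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    if isinstance(model, SRBMModel):
        rbm1 = model.rbm1.copy()
        rbm1.W = _prune_matrix(rbm1.W, fraction)
        rbm2 = None
        if model.rbm2 is not None:
            rbm2 = model.rbm2.copy()
            rbm2.W = _prune_matrix(rbm2.W, fraction)
        return SRBMModel(rbm1, rbm2, model.trace1, model.trace2,
                         model.config1, model.config2, model.gene_ids)
    pruned = model.copy()
    pruned.W = _prune_matrix(pruned.W, fraction)
    return pruned


def gene_energy(model: SRBMModel, sample, selection: NeuronSelection
                ) -> np.ndarray:
    """Per-gene circuit energy of one standardized sample (or a samples x
    genes matrix -> genes x samples energies).

    The sample is propagated in threshold mode; hidden states outside the
    selection are forced to 0 in both layers before the energy terms are
    evaluated.  The layer-2 terms carry no gene index and are added as a
    per-sample constant to every gene.
    """
    n1, n2 = model.n_hidden1, model.n_hidden2
    if selection.layer1_selected.size and (
            selection.layer1_selected.min() < 0
            or selection.layer1_selected.max() >= n1):
        raise ValueError("layer-1 selection index out of range")
    if selection.layer2_selected.size and (
            selection.layer2_selected.min() < 0
            or selection.layer2_selected.max() >= max(n2, 1)):
        raise ValueError("layer-2 selection index out of range")
    V = np.atleast_2d(np.asarray(sample, dtype=float))  # samples x genes
    h1, h2 = propagate(model, V, mode="threshold")
    mask1 = np.zeros(n1)
    mask1[selection.layer1_selected] = 1.0
    h1 = h1 * mask1
    # per-gene terms: quadratic visible energy and the gene's layer-1 circuit
    quad = 0.5 * (V - model.rbm1.B) ** 2  # samples x genes
    circuit1 = (h1 @ model.rbm1.W) * V  # samples x genes
    E = quad - circuit1
    if model.rbm2 is not None:
        mask2 = np.zeros(n2)
        mask2[selection.layer2_selected] = 1.0
        h2 = h2 * mask2
        v2 = h1  # layer-1 output feeds RBM2, already selection-masked
        const = -(v2 @ model.rbm2.B) - np.einsum(
            "sj,ji,si->s", h2, model.rbm2.W, v2)
        E = E + const[:, None]
    E = E.T  # genes x samples
    return E[:, 0] if np.asarray(sample).ndim == 1 else E


def energy_change(E1: np.ndarray, E2: np.ndarray,
                  center: bool = False) -> np.ndarray:
    """C_g = |mean over period-1 samples - mean over period-2 samples|.

    With ``center=True`` each sample's energies are first centered across
    genes.  Gene-independent energy contributions (the layer-2 terms, whose
    value is shared by every gene within a sample) then cancel exactly, so
    the change measures only the gene-specific part; without centering a
    large shared cross-period offset can dominate the absolute value and
    make the ranking follow the *signed* gene differences.
    """
    E1 = np.atleast_2d(np.asarray(E1, dtype=float))
    E2 = np.atleast_2d(np.asarray(E2, dtype=float))
    if E1.shape[0] != E2.shape[0]:
        raise ValueError("periods cover different gene sets")
    if E1.shape[1] == 0 or E2.shape[1] == 0:
        raise ValueError("each period needs at least one sample")
    if center:
        E1 = E1 - E1.mean(axis=0)
        E2 = E2 - E2.mean(axis=0)
    return np.abs(E1.mean(axis=1) - E2.mean(axis=1))


def rank_genes(C, gene_ids, E1=None, E2=None) -> GeneEnergyTable:
    """Stable descending sort on the energy change; ties keep input gene
    order; rank position 0 holds the largest change."""
    C = np.asarray(C, dtype=float)
    if len(gene_ids) != C.size:
        raise ValueError("gene_ids and C differ in length")
    if np.isnan(C).any():
        raise ValueError("energy changes contain NaN")
    order = np.argsort(-C, kind="stable")
    n = C.size
    if E1 is None:
        E1 = np.empty((n, 0))
    if E2 is None:
        E2 = np.empty((n, 0))
    return GeneEnergyTable(list(gene_ids), np.asarray(E1), np.asarray(E2),
                           C, order)


def _standardize_pooled(data1: ExpressionMatrix, data2: ExpressionMatrix):
    """Standardize per gene over the pooled samples of both periods (pooling
    keeps between-period mean shifts in the data) and split back."""
    if data1.gene_ids != data2.gene_ids:
        raise ValueError("periods must share gene set and order")
    pooled = ExpressionMatrix(
        list(data1.gene_ids),
        list(data1.sample_ids) + list(data2.sample_ids),
        np.hstack([data1.values, data2.values]),
    )
    pooled = standardize(pooled)
    n1 = data1.n_samples
    m1 = ExpressionMatrix(list(pooled.gene_ids), list(data1.sample_ids),
                          pooled.values[:, :n1], True)
    m2 = ExpressionMatrix(list(pooled.gene_ids), list(data2.sample_ids),
                          pooled.values[:, n1:], True)
    return m1, m2, pooled


def run_variant(
    data1: ExpressionMatrix,
    data2: ExpressionMatrix,
    spec: VariantSpec | str = "SRBM-II",
    cfg1: TrainingConfig | None = None,
    cfg2: TrainingConfig | None = None,
    n_hidden1: int = 400,
    n_hidden2: int = 20,
    seed: int | None = None,
    regime: str = "pooled",
    center: bool = True,
    full_output: bool = False,
):
    """End-to-end ranking for one variant.

    Standardizes the pooled data, trains the model(s), builds the unit
    selection (differential activation for the II-variants, all units with
    weak-connection pruning for the I-variants), computes per-sample gene
    energies for each period and ranks genes by the cross-period change.
    By default the energies are centered across genes within each sample
    before the change is taken (``center=True``), extending the omission of
    gene-independent energy terms to all of them; ``center=False`` keeps
    the raw per-gene energies.

    ``regime="pooled"`` (default) trains one model on all samples of both
    periods, which makes hidden units directly comparable across periods;
    ``regime="per-period"`` trains one model per period from a shared
    initialization seed and evaluates each period under its own model.
    """
    if isinstance(spec, str):
        spec = VariantSpec(name=spec)
    if regime not in ("pooled", "per-period"):
        raise ValueError(f"unknown regime {regime!r}")
    if cfg1 is None:
        cfg1 = TrainingConfig(epochs=50)
    if cfg2 is None:
        cfg2 = TrainingConfig(epochs=400, seed=cfg1.seed + 1)
    if seed is not None:
        cfg1 = TrainingConfig(**{**cfg1.__dict__, "seed": seed})
        cfg2 = TrainingConfig(**{**cfg2.__dict__, "seed": seed + 1})
    if not spec.uses_stack:
        n_hidden2 = 0
    m1, m2, pooled = _standardize_pooled(data1, data2)

    def _train(data):
        if spec.uses_stack:
            return train_srbm(data, cfg1, cfg2, n_hidden1, n_hidden2)
        from .rbm import GB, train_rbm
        rbm1, trace1 = train_rbm(data.values.T, cfg1, GB, n_hidden1)
        model = SRBMModel(rbm1, None, trace1, None, cfg1, None,
                          list(data.gene_ids))
        return model

    if regime == "pooled":
        model = _train(pooled)
        models = [model]
        prof1 = activation_frequencies(model, m1, period_id="period1")
        prof2 = activation_frequencies(model, m2, period_id="period2")
        model1 = model2 = model
    else:
        model1 = _train(m1)
        model2 = _train(m2)
        models = [model1, model2]
        prof1 = activation_frequencies(model1, m1, period_id="period1")
        prof2 = activation_frequencies(model2, m2, period_id="period2")

    if spec.uses_selection:
        diff1, diff2 = differential_activation(prof1, prof2)
        selection = select_neurons(diff1, diff2, spec.layer1_threshold,
                                   spec.layer2_threshold)
        e_model1, e_model2 = model1, model2
    else:
        selection = NeuronSelection.all_units(n_hidden1, n_hidden2)
        e_model1 = prune_weak_connections(model1, spec.prune_fraction)
        e_model2 = (e_model1 if regime == "pooled"
                    else prune_weak_connections(model2, spec.prune_fraction))

    E1 = gene_energy(e_model1, m1.values.T, selection)
    E2 = gene_energy(e_model2, m2.values.T, selection)
    C = energy_change(E1, E2, center=center)
    table = rank_genes(C, m1.gene_ids, E1, E2)
    if full_output:
        return VariantRun(table, spec, models, [prof1, prof2], selection,
                          regime)
    return table
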