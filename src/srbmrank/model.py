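"""High-level modelling interface: build a ranker from two period matrices,
fit it, inspect the results.

    >>> from srbmrank import SRBMGeneRanker
    >>> model = SRBMGeneRanker(period1, period2, variant="SRBM-II", seed=7)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.ranking  # GeneEnergyTable

The heavy lifting lives in the functional modules (:mod:`srbmrank.srbm`,
:mod:`srbmrank.ranking`); this layer packages an end-to-end run the way a
statistical model object would, keeping the fitted networks, diagnostics and
ranked table together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import data_io
from .baselines_eval import RankedList, evaluate_ranking
from .data_io import ExpressionMatrix
from .ranking import VariantRun, VariantSpec, run_variant
from .rbm import TrainingConfig

__all__ = ["SRBMGeneRanker", "SRBMGeneRankerResults"]


class SRBMGeneRanker:
    """Energy-based gene ranker over two time-period expression matrices.

    Parameters
    ----------
    period1, period2 : ExpressionMatrix
        Unstandardized genes x samples matrices sharing gene set and order
        (standardization over the pooled samples happens inside ``fit``).
    variant : str or VariantSpec
        One of RBM-I, RBM-II, SRBM-I, SRBM-II (default).
    n_hidden1, n_hidden2 : int
        Hidden-layer widths (defaults 400 and 20).
    config1, config2 : TrainingConfig, optional
        Per-layer training settings; defaults follow the standard recipe
        (eta 0.5, CD-1, 50 epochs for the Gaussian layer, 400 for the
        binary layer).
    regime : {"pooled", "per-period"}
        Whether one model is trained on all samples (default) or one per
        period.
    center : bool
        Center gene energies across genes within each sample before taking
        the cross-period change (default True); gene-independent energy
        terms then cancel exactly.
    seed : int
        Master seed; layer seeds are derived from it.
    """

    def __init__(self, period1: ExpressionMatrix, period2: ExpressionMatrix,
                 variant="SRBM-II", n_hidden1: int = 400,
                 n_hidden2: int = 20, config1: TrainingConfig | None = None,
                 config2: TrainingConfig | None = None,
                 regime: str = "pooled", center: bool = True, seed: int = 0):
        if period1.gene_ids != period2.gene_ids:
            raise ValueError("periods must share gene set and order")
        self.period1 = period1
        self.period2 = period2
        self.variant = (variant if isinstance(variant, VariantSpec)
                        else VariantSpec(name=variant))
        self.n_hidden1 = n_hidden1
        self.n_hidden2 = n_hidden2
        self.config1 = config1
        self.config2 = config2
        self.regime = regime
        self.center = center
        self.seed = seed

    @classmethod
    def from_files(cls, path1, path2, **kwargs) -> "SRBMGeneRanker":
        """Build a ranker from two expression-matrix TSV files."""
        return cls(data_io.read_expression_matrix(path1),
                   data_io.read_expression_matrix(path2), **kwargs)

    def fit(self) -> "SRBMGeneRankerResults":
        run = run_variant(
            self.period1, self.period2, self.variant,
            cfg1=self.config1, cfg2=self.config2,
            n_hidden1=self.n_hidden1, n_hidden2=self.n_hidden2,
            seed=self.seed, regime=self.regime, center=self.center,
            full_output=True,
        )
        return SRBMGeneRankerResults(self, run)


@dataclass
class SRBMGeneRankerResults:
    """Fitted ranker: trained networks, activation diagnostics, the unit
    selection, and the ranked gene-energy table."""

    model: SRBMGeneRanker
    run: VariantRun

    @property
    def ranking(self):
        return self.run.table

    @property
    def energy_changes(self) -> np.ndarray:
        return self.run.table.C

    @property
    def selection(self):
        return self.run.selection

    @property
    def traces(self) -> list:
        out = []
        for m in self.run.models:
            out.append(m.trace1)
            if m.trace2 is not None:
                out.append(m.trace2)
        return out

    def as_ranked_list(self) -> RankedList:
        return RankedList.from_energy_table(self.run.table,
                                            self.run.spec.name)

    def evaluate(self, labels):
        """ROC/PR evaluation against a labeled gene set."""
        return evaluate_ranking(self.as_ranked_list(), labels)

    def save_ranking(self, path) -> None:
        data_io.write_ranking(self.run.table, path)

    def summary(self, top: int = 10) -> str:
        """Plain-text summary: run settings, training diagnostics, unit
        selection, and the top-ranked genes."""
        run = self.run
        t = run.table
        lines = []
        w = 64
        lines.append("Energy-change gene ranking".center(w))
        lines.append("=" * w)
        lines.append(f"{'Variant:':<24}{run.spec.name}")
        lines.append(f"{'Regime:':<24}{run.regime}")
        lines.append(f"{'Genes:':<24}{len(t.gene_ids)}")
        lines.append(
            f"{'Samples:':<24}{t.E1.shape[1]} + {t.E2.shape[1]}"
        )
        m = run.models[0]
        arch = f"{m.n_visible} -> {m.n_hidden1}"
        if m.rbm2 is not None:
            arch += f" -> {m.n_hidden2}"
        lines.append(f"{'Architecture:':<24}{arch}")
        for i, trace in enumerate(self.traces):
            if len(trace):
                lines.append(
                    f"{f'Layer trace {i + 1}:':<24}"
                    f"energy {trace.energies[0]:.3f} -> "
                    f"{trace.energies[-1]:.3f} over {len(trace)} epochs"
                )
        if run.spec.uses_selection:
            lines.append(
                f"{'Selected units:':<24}"
                f"{run.selection.layer1_selected.size} (layer 1, "
                f"|dfreq| > {run.selection.layer1_threshold}), "
                f"{run.selection.layer2_selected.size} (layer 2, "
                f"|dfreq| > {run.selection.layer2_threshold})"
            )
        else:
            lines.append(
                f"{'Pruned fraction:':<24}{run.spec.prune_fraction:.3f} "
                "of each unit's fan-out"
            )
        lines.append("-" * w)
        lines.append(f"{'rank':>4}  {'gene':<16}{'energy change':>14}")
        for r in range(min(top, len(t.gene_ids))):
            g = t.gene_ids[t.rank[r]]
            lines.append(f"{r + 1:>4}  {g:<16}{t.C[t.rank[r]]:>14.4f}")
        lines.append("=" * w)
        return "\n".join(lines)
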