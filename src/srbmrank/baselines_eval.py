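"""Baseline gene rankers and the ranking-evaluation battery.

Baselines: a per-gene two-sample Welch t-test between periods (|t|
descending) and a fold-change rank-product (FC-RP) score — for every
cross-period sample pair, genes are ranked by absolute expression
difference (standardized data carry no meaningful ratio), and a gene's
score is the geometric mean of its ranks over all pairs.

Evaluation sweeps the rank cutoff over a labeled gene universe and reports
TPR (true positives recovered / all positives), FPR (false positives /
all negatives), precision and recall, with AUC and AUPR by trapezoidal
integration.  Additional comparisons: top-k list overlap and the rank
positions of the best-ranked disease genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ExpressionMatrix, GeneLabelSet

__all__ = [
    "RankedList",
    "EvalResult",
    "t_test_ranking",
    "fc_rp_ranking",
    "evaluate_ranking",
    "topk_overlap",
    "top_disease_rank_distribution",
]


@dataclass
class RankedList:
    """Genes in rank order (position 0 = most disease-like) with aligned
    scores; for score-based rankers the scores are non-increasing."""

    gene_ids: list
    scores: np.ndarray
    method_name: str = ""

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("ranked list contains duplicate genes")
        if self.scores.size != len(self.gene_ids):
            raise ValueError("scores and gene_ids differ in length")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_energy_table(cls, table, method_name: str = "") -> "RankedList":
        return cls(table.ranked_gene_ids(), table.ranked_scores(),
                   method_name)


@dataclass
class EvalResult:
    """ROC/PR curves and their areas for one ranked list."""

    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    pr_points: np.ndarray   # (n, 2) columns recall, precision
    auc: float
    aupr: float
    method_name: str = ""


def _aligned_matrices(data1: ExpressionMatrix, data2: ExpressionMatrix):
    if data1.gene_ids != data2.gene_ids:
        raise ValueError("periods must share gene set and order")
    return data1.values, data2.values


def t_test_ranking(data1: ExpressionMatrix,
                   data2: ExpressionMatrix) -> RankedList:
    """Rank genes by the absolute Welch two-sample t statistic between the
    two periods (largest first).  Genes with zero variance in both groups
    have no defined statistic and are ranked last, with a warning."""
    X1, X2 = _aligned_matrices(data1, data2)
    if X1.shape[1] < 2 or X2.shape[1] < 2:
        raise ValueError("t-test needs at least 2 samples per period")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(X1, X2, axis=1, equal_var=False)
    abs_t = np.abs(t)
    undefined = ~np.isfinite(abs_t)
    if undefined.any():
        warnings.warn(
            f"{undefined.sum()} gene(s) with zero variance in both groups "
            "ranked last",
            stacklevel=2,
        )
        abs_t = np.where(undefined, -np.inf, abs_t)
    order = np.argsort(-abs_t, kind="stable")
    return RankedList([data1.gene_ids[i] for i in order], abs_t[order],
                      "t-test")


def fc_rp_ranking(data1: ExpressionMatrix,
                  data2: ExpressionMatrix) -> RankedList:
    """Rank-product over absolute cross-period differences.

    Every pair (sample i of period 1, sample j of period 2) contributes a
    per-gene rank of |x1_i - x2_j| (rank 1 = largest difference, ties broken
    by gene order); the gene score is the geometric mean of its ranks, and
    the final list is ascending in that score (smallest rank product =
    strongest change).
    """
    X1, X2 = _aligned_matrices(data1, data2)
    n_genes = X1.shape[0]
    log_rank_sum = np.zeros(n_genes)
    n_pairs = 0
    for i in range(X1.shape[1]):
        diff = np.abs(X1[:, i][:, None] - X2)  # genes x period2 samples
        for j in range(X2.shape[1]):
            order = np.argsort(-diff[:, j], kind="stable")
            ranks = np.empty(n_genes)
            ranks[order] = np.arange(1, n_genes + 1)
            log_rank_sum += np.log(ranks)
            n_pairs += 1
    score = np.exp(log_rank_sum / n_pairs)
    order = np.argsort(score, kind="stable")
    return RankedList([data1.gene_ids[i] for i in order], score[order],
                      "FC-RP")


def evaluate_ranking(ranked: RankedList, labels: GeneLabelSet) -> EvalResult:
    """ROC/PR evaluation of a ranked list against binary disease labels.

    The evaluation universe is the labeled genes only; unlabeled genes in
    the list are ignored, and every labeled gene must appear in the list.
    Sweeping the cutoff from 0 to all labeled genes gives the curve points;
    AUC and AUPR use trapezoidal integration.
    """
    label_map = labels.as_dict()
    mask = [g in label_map for g in ranked.gene_ids]
    universe = [g for g, m in zip(ranked.gene_ids, mask) if m]
    missing = set(labels.gene_ids) - set(universe)
    if missing:
        raise ValueError(
            f"{len(missing)} labeled gene(s) missing from the ranked list "
            f"(e.g. {sorted(missing)[:3]})"
        )
    y = np.array([label_map[g] for g in universe], dtype=int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")
    tp = np.concatenate([[0], np.cumsum(y)])
    fp = np.concatenate([[0], np.cumsum(1 - y)])
    tpr = tp / n_pos
    fpr = fp / n_neg
    recall = tpr
    with np.errstate(invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    precision[0] = precision[1] if precision.size > 1 else 1.0
    auc = float(np.trapezoid(tpr, fpr))
    aupr = float(np.trapezoid(precision, recall))
    return EvalResult(np.column_stack([fpr, tpr]),
                      np.column_stack([recall, precision]),
                      auc, aupr, ranked.method_name)


def topk_overlap(a: RankedList, b: RankedList, k: int = 500):
    """Size (and fraction of k) of the intersection of the two top-k sets."""
    if k > len(a) or k > len(b):
        raise ValueError(f"k={k} exceeds a list length")
    count = len(set(a.gene_ids[:k]) & set(b.gene_ids[:k]))
    return count, count / k


def top_disease_rank_distribution(ranked: RankedList, labels: GeneLabelSet,
                                  n: int = 10) -> np.ndarray:
    """Rank positions (1-based) of the n best-ranked disease genes, for
    boxplot export."""
    label_map = labels.as_dict()
    positions = [
        i + 1
        for i, g in enumerate(ranked.gene_ids)
        if label_map.get(g, 0) == 1
    ]
    if n > len(positions):
        raise ValueError(
            f"n={n} exceeds the number of positives in the list "
            f"({len(positions)})"
        )
    return np.asarray(positions[:n], dtype=int)
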