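"""Expression-matrix and gene-label I/O, gene filtering and standardization.

Expression matrices are genes x samples, tab-separated, with a header row of
sample IDs and the first column holding gene IDs.  Lines starting with ``#``
are comments.  All downstream modelling assumes per-gene standardized values
(mean 0, population variance 1 across the pooled training samples).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneLabelSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "filter_genes",
    "filter_genes_top_n",
    "standardize",
    "read_gene_labels",
    "write_gene_labels",
    "write_ranking",
    "read_ranking",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Sample identifiers, one per column.
    values : ndarray, shape (n_genes, n_samples)
        Expression values; arbitrary units before standardization, z-units
        after.
    standardized : bool
        True once every gene row has been scaled to mean 0 / variance 1
        (constant rows map to all-zero rows).
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids),
            self.values.copy(), self.standardized,
        )


@dataclass
class GeneLabelSet:
    """Binary disease labels for a set of genes (1 = disease-related)."""

    gene_ids: list
    labels: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.gene_ids):
            raise ValueError("labels must be 1-D and match gene_ids in length")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            bad = sorted(set(self.labels) - {0, 1})
            raise ValueError(f"labels must be 0/1; found {bad}")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def as_dict(self) -> dict:
        return dict(zip(self.gene_ids, self.labels.tolist()))


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (gene IDs in first column, sample IDs in
    the header row) into an :class:`ExpressionMatrix`.

    Raises a ``ValueError`` naming the offending cell if a body entry is not
    numeric, and on duplicate gene IDs.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.index[numeric.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric expression value at gene {row!r}, "
                f"sample {col!r} in {path}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing expression value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path}"
        )
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write an expression matrix as a TSV readable by
    :func:`read_expression_matrix`."""
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")


def filter_genes(
    m: ExpressionMatrix,
    mean_quantile: float = 0.5,
    var_quantile: float = 0.5,
) -> ExpressionMatrix:
    """Keep genes with large across-sample mean AND variance.

    A gene survives if its mean is >= the ``mean_quantile`` quantile of all
    gene means and its (population) variance is >= the ``var_quantile``
    quantile of all gene variances; ties at the quantile are kept.  Row order
    is preserved.
    """
    if m.standardized:
        raise ValueError("filter_genes expects unstandardized data")
    for name, q in (("mean_quantile", mean_quantile), ("var_quantile", var_quantile)):
        if not (0.0 <= q < 1.0):
            raise ValueError(f"{name} must lie in [0, 1); got {q}")
    means = m.values.mean(axis=1)
    variances = m.values.var(axis=1)
    keep = (means >= np.quantile(means, mean_quantile)) & (
        variances >= np.quantile(variances, var_quantile)
    )
    if not keep.any():
        raise ValueError("no genes survive filter")
    return ExpressionMatrix(
        [g for g, k in zip(m.gene_ids, keep) if k],
        list(m.sample_ids),
        m.values[keep],
        standardized=False,
    )


def filter_genes_top_n(m: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Alternative filter: keep genes ranking in the top ``n`` both by mean
    and by variance (the intersection may hold fewer than ``n`` genes)."""
    if m.standardized:
        raise ValueError("filter_genes_top_n expects unstandardized data")
    if not 1 <= n <= m.n_genes:
        raise ValueError(f"n must be in [1, {m.n_genes}]; got {n}")
    means = m.values.mean(axis=1)
    variances = m.values.var(axis=1)
    top_mean = set(np.argsort(-means, kind="stable")[:n])
    top_var = set(np.argsort(-variances, kind="stable")[:n])
    keep_idx = sorted(top_mean & top_var)
    if not keep_idx:
        raise ValueError("no genes survive filter")
    return ExpressionMatrix(
        [m.gene_ids[i] for i in keep_idx],
        list(m.sample_ids),
        m.values[keep_idx],
        standardized=False,
    )


def standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene row to mean 0 and population variance 1 (divisor n).

    Constant rows cannot be scaled; they are mapped to all-zero rows with a
    warning, which makes them inert in every downstream sigmoid and energy.
    """
    if m.standardized:
        raise ValueError("matrix is already standardized")
    means = m.values.mean(axis=1, keepdims=True)
    sds = m.values.std(axis=1, keepdims=True)  # population sd (ddof=0)
    constant = sds[:, 0] == 0.0
    if constant.any():
        names = [g for g, c in zip(m.gene_ids, constant) if c]
        warnings.warn(
            f"{constant.sum()} constant gene row(s) mapped to zeros "
            f"(e.g. {names[:3]})",
            stacklevel=2,
        )
    safe_sds = np.where(sds == 0.0, 1.0, sds)
    values = (m.values - means) / safe_sds
    values[constant] = 0.0
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), values, True)


def read_gene_labels(path) -> GeneLabelSet:
    """Read a two-column (gene, label) TSV into a :class:`GeneLabelSet`.

    Labels must be 0 or 1; an empty file yields an empty set.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["gene_id", "label"], dtype={"gene_id": str})
    except pd.errors.EmptyDataError:
        return GeneLabelSet([], np.empty(0, dtype=int))
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any() or not labels.isin((0, 1)).all():
        bad = df["label"][~labels.isin((0, 1))].iloc[0]
        raise ValueError(f"gene label outside {{0,1}}: {bad!r} in {path}")
    return GeneLabelSet(list(df["gene_id"]), labels.to_numpy(dtype=int))


def write_gene_labels(labels: GeneLabelSet, path) -> None:
    pd.DataFrame({"gene_id": labels.gene_ids, "label": labels.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_ranking(table, path) -> None:
    """Write a ranked gene table as a 3-column TSV (rank, gene_id,
    energy_change); rank 1 holds the largest change."""
    order = table.rank
    pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "gene_id": [table.gene_ids[i] for i in order],
            "energy_change": table.C[order],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ranking(path) -> pd.DataFrame:
    """Read a ranking TSV back; returns a DataFrame sorted by rank."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.sort_values("rank").reset_index(drop=True)
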