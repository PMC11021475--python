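"""Bulk expression-matrix container, normalization, and gene selection.

The container is a thin wrapper over a genes-by-samples DataFrame that
tracks the unit of its values (raw counts, median-of-ratios normalized
counts, TPM, or log2) plus per-gene transcript lengths. Normalization
follows the classic bulk RNA-seq recipe: median-of-ratios size factors for
cross-sample comparability, then log2(x + 1) as the variance-stabilizing
transform feeding PCA. Within-sample abundance for rank scoring uses TPM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "aggregate_duplicate_genes",
    "compute_tpm",
    "size_factors_median_of_ratios",
    "normalize_by_size_factors",
    "log_stabilize",
    "select_top_variance_genes",
    "read_counts_tsv",
    "read_gene_lengths_tsv",
]

_UNITS = ("counts", "normalized_counts", "tpm", "log")


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression values with a declared unit.

    ``values`` rows are genes, columns are samples. ``gene_lengths`` (bp,
    indexed like the rows) is required only for TPM computation. Duplicate
    gene ids are permitted at construction for raw counts (they arise from
    many-to-one identifier conversion) and are collapsed by
    :func:`aggregate_duplicate_genes`; all other units require unique ids.
    """

    values: pd.DataFrame
    unit: str = "counts"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a genes-by-samples DataFrame")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.values.index.has_duplicates and self.unit != "counts":
            raise ValueError("duplicate gene identifiers (aggregate counts first)")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.unit != "log" and (arr < 0).any():
            raise ValueError(f"negative values are invalid for unit={self.unit!r}")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        sub = self.values.loc[self.values.index.intersection(pd.Index(genes))]
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[sub.index]
        return ExpressionMatrix(sub, unit=self.unit, gene_lengths=lengths)


def aggregate_duplicate_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Sum count rows sharing a gene id into a single row.

    Row order of first occurrence is preserved. Gene lengths of collapsed
    rows are resolved to the first occurrence's length.
    """
    if matrix.unit != "counts":
        raise ValueError("duplicate-gene aggregation applies to raw counts")
    values = matrix.values
    if not values.index.has_duplicates:
        return matrix
    order = values.index.drop_duplicates()
    summed = values.groupby(level=0, sort=False).sum().loc[order]
    lengths = None
    if matrix.gene_lengths is not None:
        lengths = matrix.gene_lengths.groupby(level=0, sort=False).first().loc[order]
    return ExpressionMatrix(summed, unit="counts", gene_lengths=lengths)


def compute_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts per million from counts and gene lengths.

    Per sample: rate_g = count_g / (length_g / 1000); TPM_g = 1e6 * rate_g
    / sum(rates). Columns of samples with any nonzero count sum to 1e6.
    """
    if counts.unit != "counts":
        raise ValueError("TPM is computed from raw counts")
    if counts.gene_lengths is None:
        raise ValueError("gene lengths are required for TPM")
    lengths = counts.gene_lengths.astype(float)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all gene lengths must be positive")
    rates = counts.values.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero sample(s); their TPM columns are zero",
            stacklevel=2,
        )
        totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return ExpressionMatrix(tpm, unit="tpm", gene_lengths=counts.gene_lengths)


def size_factors_median_of_ratios(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization rule).

    The reference for each gene is its geometric mean across samples,
    computed over genes with all-positive counts; each sample's size
    factor is the median of its count/reference ratios over those genes.
    """
    if counts.unit != "counts":
        raise ValueError("size factors are estimated from raw counts")
    values = counts.values
    if values.shape[1] < 2:
        raise ValueError("size factors require at least two samples")
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    sub = values.loc[positive].to_numpy(dtype=float)
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=values.columns, name="size_factor")


def normalize_by_size_factors(
    counts: ExpressionMatrix, size_factors: pd.Series | None = None
) -> ExpressionMatrix:
    """Divide each sample's counts by its size factor."""
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    normalized = counts.values.div(size_factors.reindex(counts.values.columns), axis=1)
    return ExpressionMatrix(normalized, unit="normalized_counts", gene_lengths=counts.gene_lengths)


def log_stabilize(normalized: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) on normalized counts; monotone within each sample."""
    if normalized.unit != "normalized_counts":
        raise ValueError("log stabilization expects median-of-ratios-normalized counts")
    return ExpressionMatrix(
        np.log2(normalized.values + 1.0), unit="log", gene_lengths=normalized.gene_lengths
    )


def select_top_variance_genes(matrix: ExpressionMatrix, fraction: float = 0.10) -> list[str]:
    """Gene ids of the ceil(fraction * n_genes) highest-variance genes.

    Variance is across samples (ddof=1) on the log matrix; ties are broken
    by input gene order.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if matrix.unit != "log":
        raise ValueError("gene selection operates on the log matrix")
    if matrix.values.shape[1] < 2:
        raise ValueError("variance requires at least two samples")
    variances = matrix.values.var(axis=1, ddof=1).to_numpy()
    n_keep = math.ceil(fraction * len(variances))
    # Stable sort on the negated variance keeps input order among ties.
    idx = np.argsort(-variances, kind="stable")[:n_keep]
    return [matrix.values.index[i] for i in idx]


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes-by-samples TSV: first column gene id, header row sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_lengths_tsv(path) -> pd.Series:
    """Two-column TSV (gene_id, length_bp) to a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]
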