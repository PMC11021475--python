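"""Rank-based single-cell cataloging, composition testing, and filtered DE.

Cells are first assigned to coarse buckets with a strict precedence rule
driven by capped-rank signature scores: a cell is *immune* if its PTPRC
score is positive, otherwise *tumor* if its melanoma-marker score (SOX10,
S100A1, MITF, MLANA, PMEL, TYR) is positive, otherwise *stroma*. Because
the capped-rank score clamps fully-out-of-rank sets to exactly zero, the
"score > 0" gate means "at least one marker gene inside the rank cap".

Composition differences between score-high and score-low sample groups
use an ordinary two-sample t-test on arcsin-square-root transformed
per-sample proportions (a propeller-style test without moderated
variance), with fold enrichment reported as the ratio of mean proportions
(high / low). Differential expression between groups uses the two-sided
Wilcoxon rank-sum test per gene with a pseudocount-1 log2 fold change and
FDR filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IMMUNE_MARKERS",
    "TUMOR_MARKERS",
    "default_marker_sets",
    "assign_bucket",
    "assign_buckets",
    "proportions_per_sample",
    "proportion_test",
    "wilcoxon_de",
    "ProportionTestResult",
]

IMMUNE_MARKERS = ["PTPRC"]
TUMOR_MARKERS = ["SOX10", "S100A1", "MITF", "MLANA", "PMEL", "TYR"]


def default_marker_sets() -> dict[str, list[str]]:
    return {"immune": list(IMMUNE_MARKERS), "tumor": list(TUMOR_MARKERS)}


@dataclass
class ProportionTestResult:
    cell_type: str
    fold_enrichment: float
    p_value: float
    fdr: float


def _capped_rank_scores(
    values: np.ndarray, gene_index: pd.Index, marker_sets: dict[str, list[str]], r_max: int
) -> dict[str, np.ndarray]:
    """Vectorized capped-rank U scores for every cell and marker set."""
    ranks = rankdata(-values, method="average", axis=1)
    scores: dict[str, np.ndarray] = {}
    for name, genes in marker_sets.items():
        cols = [gene_index.get_loc(g) for g in genes if g in gene_index]
        if not cols:
            raise ValueError(f"marker set {name!r} has no genes in the matrix")
        set_ranks = ranks[:, cols]
        all_capped = np.all(set_ranks > r_max, axis=1)
        capped = np.minimum(set_ranks, r_max + 1)
        n = len(cols)
        u = capped.sum(axis=1) - n * (n + 1) / 2.0
        s = 1.0 - u / (n * r_max)
        s[all_capped] = 0.0
        scores[name] = s
    return scores


def assign_bucket(
    cell_values: pd.Series, marker_sets: dict[str, list[str]] | None = None, r_max: int = 1500
) -> str:
    """Bucket one cell: immune -> tumor -> stroma precedence."""
    if marker_sets is None:
        marker_sets = default_marker_sets()
    frame = cell_values.to_frame().T
    labels = assign_buckets(frame, marker_sets=marker_sets, r_max=r_max)
    return str(labels.iloc[0])


def assign_buckets(
    expression: pd.DataFrame,
    marker_sets: dict[str, list[str]] | None = None,
    r_max: int = 1500,
) -> pd.Series:
    """Bucket every cell of a cells-by-genes matrix.

    Precedence order is fixed: immune if the immune-set score is > 0,
    else tumor if the tumor-set score is > 0, else stroma.
    """
    if marker_sets is None:
        marker_sets = default_marker_sets()
    for key in ("immune", "tumor"):
        if key not in marker_sets:
            raise ValueError(f"marker_sets must define an {key!r} set")
    scores = _capped_rank_scores(
        expression.to_numpy(dtype=float), expression.columns, marker_sets, r_max
    )
    labels = np.where(
        scores["immune"] > 0, "immune", np.where(scores["tumor"] > 0, "tumor", "stroma")
    )
    return pd.Series(labels, index=expression.index, name="bucket")


def proportions_per_sample(annotations: pd.DataFrame) -> pd.DataFrame:
    """Samples-by-celltype proportion matrix (rows sum to 1).

    ``annotations`` needs ``sample_id`` and ``bucket`` columns, one row
    per cell.
    """
    for col in ("sample_id", "bucket"):
        if col not in annotations.columns:
            raise ValueError(f"annotations lack column {col!r}")
    counts = pd.crosstab(annotations["sample_id"], annotations["bucket"])
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("sample with no cells")
    return counts.div(counts.sum(axis=1), axis=0)


def proportion_test(
    proportions: pd.DataFrame, group_labels: pd.Series
) -> list[ProportionTestResult]:
    """Composition test per cell type between high and low groups.

    Per cell type: arcsin(sqrt(p)) per sample, two-sample t-test between
    groups, fold enrichment = mean(high p) / mean(low p). P-values are
    FDR-adjusted across cell types; degenerate cell types (zero variance
    in both groups) get NaN p-values with a warning.
    """
    labels = pd.Series(group_labels).reindex(proportions.index)
    if labels.isna().any():
        raise ValueError("group labels missing for some samples")
    high = proportions[labels == "high"]
    low = proportions[labels == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs at least two samples")
    results = []
    pvals = []
    for cell_type in proportions.columns:
        t_high = np.arcsin(np.sqrt(high[cell_type].to_numpy(dtype=float)))
        t_low = np.arcsin(np.sqrt(low[cell_type].to_numpy(dtype=float)))
        mean_low = float(low[cell_type].mean())
        fold = float(high[cell_type].mean() / mean_low) if mean_low > 0 else float("inf")
        if np.ptp(t_high) == 0 and np.ptp(t_low) == 0 and t_high.mean() == t_low.mean():
            warnings.warn(f"cell type {cell_type!r}: degenerate proportions; test skipped")
            p = float("nan")
        else:
            p = float(ttest_ind(t_high, t_low).pvalue)
        results.append((str(cell_type), fold, p))
        pvals.append(p)
    finite = np.isfinite(pvals)
    fdr = np.full(len(pvals), np.nan)
    if finite.any():
        fdr[finite] = multipletests(np.asarray(pvals)[finite], method="fdr_bh")[1]
    return [
        ProportionTestResult(name, fold, p, float(q))
        for (name, fold, p), q in zip(results, fdr)
    ]


def wilcoxon_de(
    expression: pd.DataFrame,
    group_labels: pd.Series,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Filtered rank-sum differential expression between high and low cells.

    ``expression`` is cells-by-genes (normalized values); ``group_labels``
    maps each cell to ``high`` or ``low``. Per gene: two-sided
    Mann-Whitney/Wilcoxon rank-sum test, log2fc = log2((mean_high + 1) /
    (mean_low + 1)) (positive = higher in the high group), FDR adjustment
    across genes, then retention of genes with |log2fc| >= ``lfc_min`` and
    FDR < ``fdr_max``. ``return_all`` skips the final filter.
    """
    labels = pd.Series(group_labels).reindex(expression.index)
    if labels.isna().any():
        raise ValueError("group labels missing for some cells")
    high = expression[labels == "high"].to_numpy(dtype=float)
    low = expression[labels == "low"].to_numpy(dtype=float)
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both groups must be non-empty")
    stat, pvals = mannwhitneyu(high, low, axis=0, alternative="two-sided")
    log2fc = np.log2((high.mean(axis=0) + 1.0) / (low.mean(axis=0) + 1.0))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene_id": expression.columns,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
        }
    )
    if return_all:
        return table
    keep = (table["log2fc"].abs() >= lfc_min) & (table["fdr"] < fdr_max)
    return table[keep].reset_index(drop=True)
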