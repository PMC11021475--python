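"""TIL-culture reactivity classification and biomarker benchmarking.

Each resected metastasis seeds ~24 independent TIL fragment cultures that
are cocultured with autologous tumor and read out by 4-1BB (CD137)
upregulation on CD3+ cells (flow cytometry, percent) and IFN-gamma release
(ELISA, pg/ml), each alongside two control conditions (TIL alone and
TIL + autologous APCs). A culture counts as tumor reactive when

    4-1BB > 1%  and  4-1BB >= 2 x background,   or
    IFN-g > 100 pg/ml  and  IFN-g >= 2 x background,

where the effective background combines the two controls (the maximum by
default — the conservative choice; ``sum`` and ``apc`` rules are also
available). The per-metastasis outcome is the percentage of reactive
cultures, and biomarkers are benchmarked against it by Spearman
correlation (continuous) and by ROC/AUC for predicting >= 33% reactive
cultures (trapezoid rule; equivalent to the univariate-logistic ROC since
the logistic map is monotone in a single predictor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BenchmarkResult",
    "effective_background",
    "classify_culture",
    "classify_table",
    "percent_reactive",
    "spearman_predictor",
    "roc_auc",
    "benchmark_predictors",
    "select_response_threshold",
    "fold_change_from_log2",
]

REACTIVITY_COLUMNS = [
    "sample_id",
    "culture_id",
    "p41bb",
    "p41bb_til_alone",
    "p41bb_til_apc",
    "ifng",
    "ifng_til_alone",
    "ifng_til_apc",
]


@dataclass
class BenchmarkResult:
    predictor: str
    spearman_rho: float
    spearman_p: float
    spearman_fdr: float
    auc: float
    threshold_used: float
    n_samples: int


def effective_background(til_alone: float, til_apc: float, rule: str = "max") -> float:
    """Combine the two control readings into one background level."""
    if til_alone < 0 or til_apc < 0:
        raise ValueError("control measurements must be non-negative")
    if rule == "max":
        return float(max(til_alone, til_apc))
    if rule == "sum":
        return float(til_alone + til_apc)
    if rule == "apc":
        return float(til_apc)
    raise ValueError(f"unknown background rule {rule!r}")


def classify_culture(p41bb: float, p41bb_bg: float, ifng: float, ifng_bg: float) -> str:
    """``reactive`` / ``not_reactive`` by the dual-gate rule.

    The absolute gates (>1% 4-1BB, >100 pg/ml IFN-g) are strict; the
    twice-background comparisons are inclusive (>=). Zero background makes
    the twice-background clause trivially true, leaving the absolute gate
    as the only constraint.
    """
    if min(p41bb, p41bb_bg, ifng, ifng_bg) < 0:
        raise ValueError("reactivity measurements must be non-negative")
    by_41bb = p41bb > 1.0 and p41bb >= 2.0 * p41bb_bg
    by_ifng = ifng > 100.0 and ifng >= 2.0 * ifng_bg
    return "reactive" if (by_41bb or by_ifng) else "not_reactive"


def classify_table(table: pd.DataFrame, background_rule: str = "max") -> pd.DataFrame:
    """Per-culture classification of a reactivity assay table.

    Expects the columns in :data:`REACTIVITY_COLUMNS`; returns the table
    with added ``p41bb_bg``, ``ifng_bg`` and boolean ``reactive`` columns.
    """
    missing = [c for c in REACTIVITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"reactivity table lacks columns {missing}")
    out = table.copy()
    out["p41bb_bg"] = [
        effective_background(a, b, background_rule)
        for a, b in zip(out["p41bb_til_alone"], out["p41bb_til_apc"])
    ]
    out["ifng_bg"] = [
        effective_background(a, b, background_rule)
        for a, b in zip(out["ifng_til_alone"], out["ifng_til_apc"])
    ]
    out["reactive"] = [
        classify_culture(p, pb, i, ib) == "reactive"
        for p, pb, i, ib in zip(out["p41bb"], out["p41bb_bg"], out["ifng"], out["ifng_bg"])
    ]
    return out


def percent_reactive(classified: pd.DataFrame, sample_id: str | None = None) -> float | pd.Series:
    """100 * reactive cultures / total cultures, per metastasis.

    With ``sample_id`` returns a scalar; otherwise a per-sample Series.
    """
    if "reactive" not in classified.columns:
        raise ValueError("run classify_table first (no 'reactive' column)")
    if sample_id is not None:
        sub = classified[classified["sample_id"] == sample_id]
        if len(sub) == 0:
            raise ValueError(f"no cultures for sample {sample_id!r}")
        return float(100.0 * sub["reactive"].mean())
    grouped = classified.groupby("sample_id", sort=False)["reactive"].mean() * 100.0
    return grouped.rename("percent_reactive")


def spearman_predictor(scores, outcomes) -> tuple[float, float]:
    """Spearman rho (average-rank ties) and two-sided p of paired vectors."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and outcomes must be paired 1-d vectors")
    if len(x) < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    result = spearmanr(x, y)
    return float(result.statistic), float(result.pvalue)


def roc_auc(scores, binary_labels) -> tuple[pd.DataFrame, float]:
    """ROC over all score thresholds plus trapezoid-rule AUC.

    Tied scores are grouped at a single threshold. Requires both classes.
    """
    y = np.asarray(binary_labels).astype(int)
    x = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(y, x, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, float(_trapezoid_auc(fpr, tpr))


def benchmark_predictors(
    predictors: dict[str, pd.Series],
    outcomes: pd.Series,
    reactive_threshold: float = 33.0,
) -> list[BenchmarkResult]:
    """Benchmark biomarkers against percent-reactive outcomes.

    Per predictor: Spearman rho against the continuous percent-reactive
    values, and AUC for classifying samples with percent reactive >= the
    threshold. Spearman p-values are FDR-adjusted across predictors.
    """
    outcomes = pd.Series(outcomes, dtype=float)
    labels = (outcomes >= reactive_threshold).astype(int)
    rows = []
    for name, values in predictors.items():
        values = pd.Series(values, dtype=float).reindex(outcomes.index)
        if values.isna().any():
            raise ValueError(f"predictor {name!r} missing samples present in outcomes")
        rho, p = spearman_predictor(values.to_numpy(), outcomes.to_numpy())
        _, area = roc_auc(values.to_numpy(), labels.to_numpy())
        rows.append((name, rho, p, area))
    pvals = [p for _, _, p, _ in rows]
    if all(np.isfinite(pvals)):
        fdr = multipletests(pvals, method="fdr_bh")[1]
    else:
        fdr = [float("nan")] * len(pvals)
    return [
        BenchmarkResult(name, rho, p, float(q), area, float(reactive_threshold), len(outcomes))
        for (name, rho, p, area), q in zip(rows, fdr)
    ]


def select_response_threshold(scores: pd.Series, responder_flags: pd.Series) -> float:
    """Median score among nonresponders, used as a response cutoff."""
    scores = pd.Series(scores, dtype=float)
    flags = pd.Series(responder_flags).astype(bool).reindex(scores.index)
    nonresponders = scores[~flags]
    if len(nonresponders) == 0:
        raise ValueError("no nonresponders to define a threshold")
    return float(nonresponders.median())


def fold_change_from_log2(log2_fold_change: float) -> float:
    """Linear fold change of magnitude ``2 ** |log2fc|``.

    Reported fold changes are magnitudes: a gene with log2fc = -1.80
    (down in the high group) is a 3.48-fold difference.
    """
    return float(2.0 ** abs(log2_fold_change))
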