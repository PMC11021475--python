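"""Single-sample rank-based gene-set scoring.

Two engines live here:

* the singscore-style normalized mean-rank score used for bulk biopsies
  (unidirectional "expected up" mode, plus a bidirectional mode that adds
  an expected-down component computed on reversed ranks), and
* a capped-rank Mann-Whitney U score for single cells, in which genes are
  ranked in *descending* order of expression and any rank beyond ``r_max``
  is truncated to ``r_max + 1``.

Both scores are functions of within-sample ranks only, so they are
invariant under any strictly increasing transform of a sample's expression
vector and are therefore usable one sample at a time, with no cohort or
batch context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SampleScore",
    "rank_within_sample",
    "singscore_up",
    "singscore_bidirectional",
    "umis",
    "dichotomize_by_median",
    "ucell_score",
]


@dataclass
class SampleScore:
    """A per-sample signature score.

    Attributes
    ----------
    sample_id:
        Identifier of the scored sample (may be ``None`` for ad-hoc vectors).
    score:
        The enrichment score. Uncentered unidirectional scores lie in
        [0, 1]; centered ones in [-0.5, 0.5]; centered bidirectional totals
        in [-1, 1].
    mode:
        ``"unidirectional"`` or ``"bidirectional"``.
    centered:
        Whether 0.5 per direction was subtracted.
    set_size_used:
        Number of signature genes actually found in the sample's gene
        universe (genes absent from the universe are dropped per sample).
    """

    sample_id: str | None
    score: float
    mode: str
    centered: bool
    set_size_used: int
    down_set_size_used: int | None = None


def rank_within_sample(values: Sequence[float] | pd.Series) -> np.ndarray:
    """Ascending 1..N ranks of a sample's expression vector, ties averaged."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("rank_within_sample requires at least one gene")
    return rankdata(arr, method="average")


def _as_series(sample_values) -> pd.Series:
    if isinstance(sample_values, pd.Series):
        return sample_values
    raise TypeError(
        "sample_values must be a pandas Series indexed by gene id; "
        f"got {type(sample_values).__name__}"
    )


def _mean_set_rank(ranks: pd.Series, genes: Sequence[str]) -> tuple[float, int]:
    present = ranks.index.intersection(pd.Index(genes))
    n_dropped = len(set(genes)) - len(present)
    if len(present) == 0:
        raise ValueError("gene set has empty intersection with the sample's gene universe")
    if n_dropped:
        warnings.warn(
            f"{n_dropped} signature gene(s) absent from the sample universe were dropped",
            stacklevel=3,
        )
    return float(ranks.loc[present].mean()), int(len(present))


def _normalize_mean_rank(meanrank: float, n_set: int, n_universe: int) -> float:
    # Theoretical extremes of the mean rank: the set packed at the bottom
    # of the ranking versus packed at the top.
    min_mean = (n_set + 1) / 2.0
    max_mean = (2 * n_universe - n_set + 1) / 2.0
    if max_mean == min_mean:
        raise ValueError("gene set must be a strict subset of the universe")
    return (meanrank - min_mean) / (max_mean - min_mean)


def singscore_up(
    sample_values: pd.Series,
    up_set: Iterable[str],
    centered: bool = False,
    sample_id: str | None = None,
) -> SampleScore:
    """Unidirectional expected-up singscore of one sample.

    The score is the mean ascending rank of the set genes, min-max
    normalized to [0, 1] by its theoretical extremes; ``centered``
    subtracts 0.5 so that a random gene set is expected near zero.
    """
    values = _as_series(sample_values)
    up = list(dict.fromkeys(up_set))
    if len(up) == 0:
        raise ValueError("up_set is empty")
    ranks = pd.Series(rank_within_sample(values.to_numpy()), index=values.index)
    meanrank, n_used = _mean_set_rank(ranks, up)
    if n_used >= len(values):
        raise ValueError("gene set covers the whole universe; score undefined")
    score = _normalize_mean_rank(meanrank, n_used, len(values))
    if centered:
        score -= 0.5
    return SampleScore(sample_id, float(score), "unidirectional", centered, n_used)


def singscore_bidirectional(
    sample_values: pd.Series,
    up_set: Iterable[str],
    down_set: Iterable[str],
    centered: bool = True,
    sample_id: str | None = None,
) -> SampleScore:
    """Bidirectional singscore: expected-up plus expected-down components.

    The down component applies the same normalized mean-rank formula to
    reversed ranks (rank -> N + 1 - rank), so genes expected to be lowly
    expressed contribute positively when they indeed rank low. Centered
    components each lie in [-0.5, 0.5] and their sum in [-1, 1]. An empty
    down set is rejected: use :func:`singscore_up` for unidirectional use.
    """
    values = _as_series(sample_values)
    up = list(dict.fromkeys(up_set))
    down = list(dict.fromkeys(down_set))
    if len(up) == 0 or len(down) == 0:
        raise ValueError("bidirectional scoring requires non-empty up and down sets")
    if set(up) & set(down):
        raise ValueError("up and down sets overlap")
    n_universe = len(values)
    ranks = pd.Series(rank_within_sample(values.to_numpy()), index=values.index)
    up_mean, n_up = _mean_set_rank(ranks, up)
    rev = (n_universe + 1) - ranks
    down_mean, n_down = _mean_set_rank(rev, down)
    up_score = _normalize_mean_rank(up_mean, n_up, n_universe)
    down_score = _normalize_mean_rank(down_mean, n_down, n_universe)
    if centered:
        up_score -= 0.5
        down_score -= 0.5
    total = up_score + down_score
    return SampleScore(sample_id, float(total), "bidirectional", centered, n_up, n_down)


def umis(tpm, signature, centered: bool = False) -> list[SampleScore]:
    """Score every sample of a TPM matrix against a signature.

    Parameters
    ----------
    tpm:
        :class:`~umiskit.expression.ExpressionMatrix` in TPM (or any
        within-sample monotone-equivalent unit); genes x samples.
    signature:
        A :class:`~umiskit.discovery.Signature`, or any object with a
        ``gene_ids`` attribute, or a plain iterable of gene ids.
    centered:
        Subtract 0.5 from each score (default reports the raw [0, 1]
        normalized mean percentile rank).
    """
    gene_ids = getattr(signature, "gene_ids", signature)
    frame = getattr(tpm, "values", tpm)
    if not isinstance(frame, pd.DataFrame):
        raise TypeError("tpm must be an ExpressionMatrix or genes-by-samples DataFrame")
    return [
        singscore_up(frame[s], gene_ids, centered=centered, sample_id=str(s))
        for s in frame.columns
    ]


def dichotomize_by_median(scores) -> pd.Series:
    """Split samples into ``high``/``low`` at the cohort median score.

    ``high`` means strictly above the median; scores tied with the median
    fall in the ``low`` group.
    """
    if isinstance(scores, (list, tuple)) and scores and isinstance(scores[0], SampleScore):
        scores = pd.Series({s.sample_id: s.score for s in scores})
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least two samples to dichotomize")
    med = float(s.median())
    return pd.Series(np.where(s.to_numpy() > med, "high", "low"), index=s.index)


def ucell_score(
    cell_values: pd.Series,
    gene_set: Iterable[str],
    r_max: int = 1500,
) -> float:
    """Capped-rank U-statistic signature score of one cell, in [0, 1].

    Genes are ranked in descending order of expression (ties averaged) and
    ranks beyond ``r_max`` are truncated to ``r_max + 1``. With n set genes,
    ``U = sum(capped set ranks) - n(n+1)/2`` and the score is
    ``1 - U / (n * r_max)``. A set whose genes are all beyond the rank cap
    is clamped to exactly 0 (the raw formula would leave a small positive
    floor of (n-1)/(2*r_max), which would make "score > 0" gating rules
    ill-defined).
    """
    values = _as_series(cell_values)
    genes = list(dict.fromkeys(gene_set))
    if len(genes) == 0:
        raise ValueError("gene_set is empty")
    if r_max < 1:
        raise ValueError("r_max must be a positive integer")
    present = values.index.intersection(pd.Index(genes))
    if len(present) == 0:
        raise ValueError("gene set has empty intersection with the cell's gene universe")
    ranks = pd.Series(rankdata(-values.to_numpy(), method="average"), index=values.index)
    set_ranks = ranks.loc[present].to_numpy(dtype=float)
    if np.all(set_ranks > r_max):
        return 0.0
    capped = np.minimum(set_ranks, r_max + 1)
    n = len(present)
    u = float(capped.sum()) - n * (n + 1) / 2.0
    return float(1.0 - u / (n * r_max))
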