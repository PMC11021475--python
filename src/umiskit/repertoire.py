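"""TCR repertoire analytics on tabulated clonotype counts.

A clonotype is identified by its chain (TRA or TRB) plus amino-acid CDR3
sequence; V/J gene usage is ignored. Per sample and chain the module
reports richness S, Shannon diversity H = -sum p_i ln p_i (natural log),
and clonality = 1 - Pielou's evenness = 1 - H/ln S. Clonality is
undefined for S <= 1, so such samples are excluded per chain. Sharing
analysis labels a clonotype public when it occurs in two or more samples.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "VALID_CDR3",
    "tabulate_clonotypes",
    "shannon_diversity",
    "clonality",
    "repertoire_metrics",
    "filter_low_richness",
    "sharing_summary",
    "diversity_delta",
]

VALID_CDR3 = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

_AIRR_ALIASES = {"junction_aa": "cdr3_aa", "duplicate_count": "count", "locus": "chain"}


def tabulate_clonotypes(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw clonotype rows to unique (sample, chain, cdr3_aa) records.

    Accepts AIRR-style column aliases (junction_aa, duplicate_count,
    locus). Rows with malformed CDR3 (non-amino-acid characters) are
    dropped with a warning; duplicate keys have their counts summed.
    """
    table = raw.rename(columns=_AIRR_ALIASES).copy()
    required = ["sample_id", "chain", "cdr3_aa", "count"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"clonotype table lacks columns {missing}")
    if len(table) == 0:
        return table[required]
    if (table["count"] < 1).any():
        raise ValueError("clonotype counts must be positive")
    valid = table["cdr3_aa"].astype(str).str.match(VALID_CDR3)
    if not valid.all():
        warnings.warn(f"rejected {int((~valid).sum())} row(s) with malformed CDR3")
        table = table[valid]
    out = (
        table.groupby(["sample_id", "chain", "cdr3_aa"], sort=False, as_index=False)["count"]
        .sum()
    )
    return out[required]


def shannon_diversity(counts) -> float:
    """Shannon index H = -sum p_i ln p_i in natural-log units."""
    arr = np.asarray(counts, dtype=float)
    if arr.size < 1:
        raise ValueError("at least one clone required")
    if (arr <= 0).any():
        raise ValueError("clone counts must be positive")
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def clonality(counts) -> float:
    """1 - Pielou's evenness = 1 - H / ln(S); undefined for S < 2."""
    arr = np.asarray(counts, dtype=float)
    if arr.size < 2:
        raise ValueError("clonality is undefined for fewer than two clonotypes")
    return float(1.0 - shannon_diversity(arr) / np.log(arr.size))


def repertoire_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, chain) richness, Shannon diversity, and clonality.

    Samples with one or zero unique clonotypes for a chain are flagged
    ``excluded`` with clonality (and diversity, for S=0) set to NaN.
    """
    rows = []
    for (sample_id, chain), group in table.groupby(["sample_id", "chain"], sort=False):
        counts = group["count"].to_numpy(dtype=float)
        richness = len(counts)
        excluded = richness <= 1
        h = shannon_diversity(counts) if richness >= 1 else float("nan")
        c = clonality(counts) if richness >= 2 else float("nan")
        rows.append(
            {
                "sample_id": sample_id,
                "chain": chain,
                "richness": richness,
                "shannon": h,
                "clonality": c,
                "excluded": excluded,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "chain", "richness", "shannon", "clonality", "excluded"]
    )


def filter_low_richness(metrics: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split metrics rows into (kept, excluded) by the S <= 1 rule."""
    excluded = metrics[metrics["excluded"]]
    kept = metrics[~metrics["excluded"]]
    return kept, excluded


def sharing_summary(table: pd.DataFrame, chain: str) -> pd.DataFrame:
    """Public/private labeling of clonotypes of one chain across samples.

    Returns one row per unique CDR3 with the number of samples carrying
    it and ``public`` = occurrence in >= 2 samples.
    """
    sub = table[table["chain"] == chain]
    n_samples = table["sample_id"].nunique()
    if n_samples < 2:
        raise ValueError("sharing analysis requires at least two samples")
    occurrence = (
        sub.groupby("cdr3_aa", sort=False)["sample_id"].nunique().rename("n_samples")
    )
    out = occurrence.reset_index()
    out["public"] = out["n_samples"] >= 2
    return out


def diversity_delta(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Paired (post - pre) differences of diversity and clonality.

    Inputs are metrics frames from :func:`repertoire_metrics` covering the
    same samples and a single chain each; suitable for a paired
    signed-rank test downstream.
    """
    key = ["sample_id"]
    pre_idx = pre.set_index(key)
    post_idx = post.set_index(key)
    if set(pre_idx.index) != set(post_idx.index):
        raise ValueError("pre and post metrics cover different samples")
    post_idx = post_idx.reindex(pre_idx.index)
    return pd.DataFrame(
        {
            "sample_id": pre_idx.index,
            "delta_shannon": (post_idx["shannon"] - pre_idx["shannon"]).to_numpy(),
            "delta_clonality": (post_idx["clonality"] - pre_idx["clonality"]).to_numpy(),
        }
    )
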