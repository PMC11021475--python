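"""Unsupervised discovery of the immune transcriptional axis.

The discovery procedure works on a cohort of bulk tumor biopsies:

1. PCA of the log-stabilized matrix restricted to the top-variance genes
   (samples as observations, genes centered, no unit-variance scaling).
2. Per-sample enrichment of hallmark-style gene sets via the
   unidirectional singscore (cohort-independent, one sample at a time).
3. Spearman correlation of each gene set's enrichment with each leading
   PC coordinate, then complete-linkage hierarchical clustering of the
   correlation profiles (Euclidean distance) into biologic motifs.
4. Identification of the immune axis: the candidate PC whose mean
   correlation with a named list of immune/inflammatory sets has the
   largest magnitude, with the direction given by the sign of that mean.
5. Signature selection: every PCA-input gene whose loading on the immune
   PC has the sign matching the immune direction. No supervised filtering
   is applied on top of the sign rule.

The per-sample singscore of the resulting signature is the tumor's
immunogenomic score (UMIS in the uveal-melanoma setting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .expression import ExpressionMatrix, select_top_variance_genes
from .genesets import GeneSetCollection
from .scoring import singscore_up

__all__ = [
    "PcaResult",
    "CorrelationMatrix",
    "Signature",
    "run_pca",
    "score_genesets_per_sample",
    "correlate_pcs_with_genesets",
    "cluster_genesets",
    "identify_immune_axis",
    "select_signature",
    "candidate_pcs",
    "discover_signature",
]


@dataclass
class PcaResult:
    """PCA decomposition: per-sample coordinates and per-gene loadings.

    ``scores`` is samples x PCs, ``loadings`` genes x PCs (orthonormal
    columns), ``explained_variance_fraction`` is per-PC and descending.
    Sign convention: within each PC the largest-magnitude loading is
    positive, which makes the decomposition deterministic.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray

    def pc_name(self, index: int) -> str:
        return f"PC{index}"


@dataclass
class CorrelationMatrix:
    """Gene-set by PC Spearman correlations, plus optional cluster labels."""

    rho: pd.DataFrame
    cluster_labels: pd.Series | None = None


@dataclass
class Signature:
    """A discovered gene signature with its provenance."""

    gene_ids: list[str]
    source_pc: int
    direction: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(dict.fromkeys(self.gene_ids))
        if not self.gene_ids:
            raise ValueError("signature is empty")
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")

    def __len__(self) -> int:
        return len(self.gene_ids)


def run_pca(matrix: ExpressionMatrix, n_components: int) -> PcaResult:
    """PCA of a log expression matrix (genes centered across samples)."""
    if matrix.unit != "log":
        raise ValueError("PCA expects the log-stabilized matrix")
    data = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n_samples, n_genes = data.shape
    if n_components > min(n_genes, n_samples - 1):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_genes, n_samples - 1)="
            f"{min(n_genes, n_samples - 1)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data)
    loadings = pca.components_.T  # genes x PCs
    # Deterministic orientation: largest-|loading| gene positive per PC.
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    pc_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns, columns=pc_names),
        loadings=pd.DataFrame(loadings, index=matrix.values.index, columns=pc_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def score_genesets_per_sample(
    tpm: ExpressionMatrix, sets: GeneSetCollection
) -> pd.DataFrame:
    """Samples-by-sets matrix of unidirectional singscores on TPM.

    Each score depends only on its own sample's ranks, so adding or
    removing samples never changes the others. Sets with no genes in the
    matrix are dropped with a warning.
    """
    universe = pd.Index(tpm.gene_ids)
    columns: dict[str, list[float]] = {}
    for gs in sets:
        genes = [g for g in gs.up if g in universe]
        if not genes:
            warnings.warn(f"gene set {gs.name!r} has no genes in the matrix; skipped")
            continue
        columns[gs.name] = [
            singscore_up(tpm.values[s], genes, sample_id=str(s)).score
            for s in tpm.values.columns
        ]
    return pd.DataFrame(columns, index=tpm.values.columns)


def correlate_pcs_with_genesets(
    pca: PcaResult, set_scores: pd.DataFrame, pcs: list[int] | None = None
) -> CorrelationMatrix:
    """Spearman rho of each gene set's enrichment against each PC coordinate."""
    if pcs is None:
        pcs = [1, 2, 3]
    pc_cols = [f"PC{i}" for i in pcs]
    missing = [c for c in pc_cols if c not in pca.scores.columns]
    if missing:
        raise ValueError(f"PCA result lacks components {missing}")
    if not pca.scores.index.equals(set_scores.index):
        set_scores = set_scores.reindex(pca.scores.index)
        if set_scores.isna().any().any():
            raise ValueError("PC scores and gene-set scores cover different samples")
    rho = pd.DataFrame(index=set_scores.columns, columns=pc_cols, dtype=float)
    for set_name in set_scores.columns:
        y = set_scores[set_name].to_numpy()
        for pc in pc_cols:
            x = pca.scores[pc].to_numpy()
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                rho.loc[set_name, pc] = np.nan
                continue
            rho.loc[set_name, pc] = spearmanr(x, y).statistic
    return CorrelationMatrix(rho=rho)


def cluster_genesets(corr: CorrelationMatrix, k: int = 4) -> pd.Series:
    """Complete-linkage Euclidean clustering of correlation profiles."""
    rho = corr.rho.dropna(axis=0, how="any")
    if k > len(rho):
        raise ValueError(f"k={k} exceeds the {len(rho)} clusterable gene sets")
    z = linkage(rho.to_numpy(dtype=float), method="complete", metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust")
    result = pd.Series(labels, index=rho.index, name="cluster")
    corr.cluster_labels = result
    return result


def identify_immune_axis(
    corr: CorrelationMatrix, immune_set_names: list[str]
) -> tuple[int, str, float]:
    """Locate the PC carrying the immune/inflammatory program.

    Over candidate PCs (the columns of ``corr.rho``), returns the PC index
    maximizing the magnitude of the mean Spearman rho over the named
    immune sets, with direction = sign of that mean, and an exclusivity
    diagnostic (winning |mean rho| over runner-up |mean rho|). Ties in
    |mean rho| go to the lower PC index.
    """
    missing = [n for n in immune_set_names if n not in corr.rho.index]
    if missing:
        raise ValueError(f"immune sets not among scored sets: {missing}")
    means = corr.rho.loc[immune_set_names].mean(axis=0)
    if means.isna().all() or (means.abs().fillna(0) == 0).all():
        raise ValueError("no immune axis detected: all mean correlations zero or missing")
    magnitudes = means.abs().fillna(0.0)
    ranked = sorted(
        magnitudes.items(), key=lambda item: (-item[1], int(item[0].lstrip("PC")))
    )
    winner, win_mag = ranked[0]
    runner_mag = ranked[1][1] if len(ranked) > 1 else 0.0
    exclusivity = float(win_mag / runner_mag) if runner_mag > 0 else float("inf")
    pc_index = int(winner.lstrip("PC"))
    direction = "positive" if means[winner] > 0 else "negative"
    return pc_index, direction, exclusivity


def select_signature(pca: PcaResult, pc_index: int, direction: str, provenance: dict | None = None) -> Signature:
    """All PCA-input genes whose loading sign on ``pc_index`` matches ``direction``.

    Strictly positive loadings for ``direction='positive'``, strictly
    negative for ``'negative'``; zero loadings are never selected.
    """
    col = f"PC{pc_index}"
    if col not in pca.loadings.columns:
        raise ValueError(f"{col} not in PCA result")
    loadings = pca.loadings[col]
    if direction == "positive":
        genes = loadings.index[loadings > 0]
    elif direction == "negative":
        genes = loadings.index[loadings < 0]
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    if len(genes) == 0:
        raise ValueError("signature selection produced no genes")
    prov = dict(provenance or {})
    prov.update(
        {
            "source_pc": pc_index,
            "direction": direction,
            "n_pca_genes": int(pca.loadings.shape[0]),
            "n_selected": int(len(genes)),
        }
    )
    return Signature(list(genes), source_pc=pc_index, direction=direction, provenance=prov)


def candidate_pcs(
    pca: PcaResult, min_variance_fraction: float = 0.05, max_pcs: int = 3
) -> list[int]:
    """Leading PCs explaining more than ``min_variance_fraction``, capped."""
    keep = [
        i + 1
        for i, frac in enumerate(pca.explained_variance_fraction)
        if frac > min_variance_fraction
    ]
    keep = keep[:max_pcs]
    return keep or [1]


@dataclass
class DiscoveryResult:
    pca: PcaResult
    set_scores: pd.DataFrame
    correlations: CorrelationMatrix
    cluster_labels: pd.Series
    signature: Signature
    immune_pc: int
    immune_direction: str
    exclusivity: float
    top_variance_genes: list[str]


def discover_signature(
    log_matrix: ExpressionMatrix,
    tpm: ExpressionMatrix,
    sets: GeneSetCollection,
    immune_set_names: list[str],
    top_fraction: float = 0.10,
    n_components: int | None = None,
    n_clusters: int = 4,
    min_variance_fraction: float = 0.05,
    max_candidate_pcs: int = 3,
) -> DiscoveryResult:
    """Run the full discovery procedure on a cohort.

    ``n_components`` defaults to min(10, n_samples - 1).
    """
    top_genes = select_top_variance_genes(log_matrix, fraction=top_fraction)
    restricted = log_matrix.subset_genes(top_genes)
    if n_components is None:
        n_components = min(10, restricted.values.shape[1] - 1, len(top_genes))
    pca = run_pca(restricted, n_components=n_components)
    pcs = candidate_pcs(pca, min_variance_fraction, max_candidate_pcs)
    set_scores = score_genesets_per_sample(tpm, sets)
    corr = correlate_pcs_with_genesets(pca, set_scores, pcs=pcs)
    clusters = cluster_genesets(corr, k=min(n_clusters, len(corr.rho.dropna())))
    pc_index, direction, exclusivity = identify_immune_axis(corr, immune_set_names)
    signature = select_signature(
        pca,
        pc_index,
        direction,
        provenance={
            "top_fraction": top_fraction,
            "n_components": n_components,
            "candidate_pcs": pcs,
            "immune_set_names": list(immune_set_names),
            "exclusivity": exclusivity,
        },
    )
    return DiscoveryResult(
        pca=pca,
        set_scores=set_scores,
        correlations=corr,
        cluster_labels=clusters,
        signature=signature,
        immune_pc=pc_index,
        immune_direction=direction,
        exclusivity=exclusivity,
        top_variance_genes=top_genes,
    )
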