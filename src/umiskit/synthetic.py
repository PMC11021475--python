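"""Seeded synthetic cohort generator for end-to-end pipeline testing.

The generator emulates the statistical structure the analysis assumes in a
cohort of tumor metastases, at desk scale, with known ground truth:

* a latent per-sample inflammation level ``theta`` in [0, 1] driving a
  planted immune gene program in negative-binomial bulk counts, alongside
  decoy covariance programs (metabolic/liver-like) driven by independent
  latent factors;
* TIL-culture reactivity outcomes linked to ``theta`` through a logistic
  link, with assay values constructed to respect the dual-gate
  classification rule (absolute gate plus twice-background);
* TCR repertoires whose richness grows with ``theta`` and whose clone
  sizes are geometric;
* marker-gene-structured single cells in three buckets (immune cells
  express PTPRC, tumor cells express the melanoma markers, stroma cells
  express neither);
* an independent tumor-mutational-burden covariate, included purely as a
  benchmarking foil (it carries no information about reactivity).

One global integer seed drives a hierarchy of per-component substreams
(theta, bulk, reactivity, repertoire, cells, covariates) so that each
component can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import IMMUNE_MARKERS, TUMOR_MARKERS
from .expression import ExpressionMatrix
from .genesets import GeneSet, GeneSetCollection, write_gmt

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "MARKER_GENES",
    "simulate_bulk_counts",
    "simulate_reactivity",
    "simulate_repertoire",
    "simulate_repertoires",
    "simulate_cells",
    "build_fixture_genesets",
    "IMMUNE_FIXTURE_SET_NAMES",
    "write_cohort",
]

MARKER_GENES = list(IMMUNE_MARKERS) + list(TUMOR_MARKERS)

_AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Substream labels -> index into the spawned seed sequence hierarchy.
_STREAMS = {"theta": 0, "bulk": 1, "reactivity": 2, "repertoire": 3, "cells": 4, "covariates": 5}


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults define the study conditions.

    ``immune_effect`` is the log2-scale shift of immune-gene means between
    theta = 0 and theta = 1; ``nb_dispersion`` is the negative-binomial
    dispersion alpha (variance = mu + alpha * mu^2);
    ``baseline_log_mean_range`` bounds per-gene baseline log2 means;
    ``reactivity_slope``/``reactivity_intercept`` parameterize the
    logistic link from theta to the per-culture reactivity probability;
    ``repertoire_decay`` is the geometric clone-size parameter;
    ``n_sc_samples_per_group`` picks that many highest- and lowest-theta
    samples for single-cell simulation.
    """

    n_samples: int = 60
    n_genes: int = 2000
    n_immune_genes: int = 150
    n_decoy_programs: int = 2
    decoy_program_size: int = 25
    immune_effect: float = 2.0
    nb_dispersion: float = 0.02
    baseline_log_mean_range: tuple[float, float] = (5.0, 9.0)
    n_cultures_per_sample: int = 24
    reactivity_slope: float = 6.0
    reactivity_intercept: float = -3.0
    repertoire_clones_range: tuple[int, int] = (5, 250)
    repertoire_decay: float = 0.1
    n_cells_per_sample: int = 500
    n_sc_samples_per_group: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_immune_genes) < 1:
            raise ValueError("cohort dimensions must be positive")
        planted = self.n_immune_genes + self.n_decoy_programs * self.decoy_program_size
        if planted + len(MARKER_GENES) > self.n_genes:
            raise ValueError(
                f"planted programs ({planted}) plus marker genes exceed n_genes={self.n_genes}"
            )
        for name in ("baseline_log_mean_range", "repertoire_clones_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy lower <= upper")
        if self.immune_effect < 0:
            raise ValueError("immune_effect must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0 < self.repertoire_decay <= 1):
            raise ValueError("repertoire_decay must lie in (0, 1]")
        if self.n_sc_samples_per_group * 2 > self.n_samples:
            raise ValueError("n_sc_samples_per_group exceeds half the cohort")

    def rng(self, stream: str) -> np.random.Generator:
        """Named per-component random substream under the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class CohortTruth:
    """Generator ground truth for parameter-recovery tests."""

    theta: pd.Series
    immune_gene_ids: list[str]
    decoy_gene_ids: list[list[str]]
    true_reactive_fraction: pd.Series
    tmb: pd.Series
    cell_true_bucket: pd.Series | None = None

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if not np.all(np.isfinite(theta)) or theta.min() < 0 or theta.max() > 1:
            raise ValueError("theta must be finite and within [0, 1]")
        decoys = {g for program in self.decoy_gene_ids for g in program}
        if decoys & set(self.immune_gene_ids):
            raise ValueError("immune and decoy gene lists must be disjoint")


def _gene_universe(config: CohortConfig) -> tuple[list[str], list[str], list[list[str]]]:
    """Gene ids: planted immune, decoy programs, markers, background."""
    immune = [f"IMM{i + 1:04d}" for i in range(config.n_immune_genes)]
    decoys = [
        [f"DEC{k + 1}_{i + 1:03d}" for i in range(config.decoy_program_size)]
        for k in range(config.n_decoy_programs)
    ]
    n_rest = config.n_genes - len(immune) - sum(len(d) for d in decoys) - len(MARKER_GENES)
    rest = [f"GENE{i + 1:04d}" for i in range(n_rest)]
    universe = immune + [g for d in decoys for g in d] + list(MARKER_GENES) + rest
    return universe, immune, decoys


def simulate_bulk_counts(config: CohortConfig) -> tuple[ExpressionMatrix, CohortTruth]:
    """Negative-binomial bulk counts with a planted immune program.

    Per-gene baseline log2 means are uniform in
    ``baseline_log_mean_range``; immune genes gain
    ``immune_effect * theta_j`` in sample j, and each decoy program gains
    the same effect times its own independent uniform latent factor.
    Identical (config, seed) pairs yield bit-identical output.
    """
    rng_theta = config.rng("theta")
    rng = config.rng("bulk")
    rng_cov = config.rng("covariates")

    sample_ids = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    theta = pd.Series(rng_theta.uniform(0.0, 1.0, config.n_samples), index=sample_ids, name="theta")

    universe, immune, decoys = _gene_universe(config)
    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, config.n_genes)

    log2_mu = np.tile(baseline[:, None], (1, config.n_samples))
    gene_pos = {g: i for i, g in enumerate(universe)}
    immune_rows = [gene_pos[g] for g in immune]
    log2_mu[immune_rows, :] += config.immune_effect * theta.to_numpy()[None, :]
    for program in decoys:
        z = rng.uniform(0.0, 1.0, config.n_samples)
        rows = [gene_pos[g] for g in program]
        log2_mu[rows, :] += config.immune_effect * z[None, :]

    mu = np.exp2(log2_mu)
    alpha = config.nb_dispersion
    n_param = 1.0 / alpha
    p_param = 1.0 / (1.0 + alpha * mu)
    counts = rng.negative_binomial(n_param, p_param)

    lengths = pd.Series(
        rng.integers(200, 10001, config.n_genes), index=universe, name="length_bp"
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=universe, columns=sample_ids),
        unit="counts",
        gene_lengths=lengths,
    )

    link = config.reactivity_intercept + config.reactivity_slope * theta.to_numpy()
    reactive_fraction = pd.Series(1.0 / (1.0 + np.exp(-link)), index=sample_ids)
    tmb = pd.Series(
        rng_cov.lognormal(mean=np.log(0.64), sigma=0.8, size=config.n_samples),
        index=sample_ids,
        name="tmb",
    )
    truth = CohortTruth(
        theta=theta,
        immune_gene_ids=immune,
        decoy_gene_ids=decoys,
        true_reactive_fraction=reactive_fraction,
        tmb=tmb,
    )
    return matrix, truth


def simulate_reactivity(theta: pd.Series, config: CohortConfig) -> pd.DataFrame:
    """Per-culture reactivity assay table linked to theta.

    Each of ``n_cultures_per_sample`` cultures is truly reactive with
    probability logistic(intercept + slope * theta). Truly reactive
    cultures receive 4-1BB and IFN-gamma readings above both the absolute
    gates and twice their simulated controls; non-reactive cultures stay
    below the absolute gates on both axes. Controls carry positive noise.
    """
    rng = config.rng("reactivity")
    theta = pd.Series(theta, dtype=float)
    if ((theta < 0) | (theta > 1)).any():
        raise ValueError("theta must lie in [0, 1]")
    rows = []
    for sample_id, t in theta.items():
        p = 1.0 / (1.0 + np.exp(-(config.reactivity_intercept + config.reactivity_slope * t)))
        for c in range(config.n_cultures_per_sample):
            reactive = rng.random() < p
            bg41_alone = rng.uniform(0.05, 0.6)
            bg41_apc = rng.uniform(0.05, 0.6)
            bgif_alone = rng.uniform(5.0, 60.0)
            bgif_apc = rng.uniform(5.0, 60.0)
            if reactive:
                p41bb = max(1.0, 2.0 * max(bg41_alone, bg41_apc)) * rng.uniform(1.5, 6.0)
                ifng = max(100.0, 2.0 * max(bgif_alone, bgif_apc)) * rng.uniform(1.5, 6.0)
            else:
                p41bb = rng.uniform(0.0, 0.8)
                ifng = rng.uniform(0.0, 90.0)
            rows.append(
                {
                    "sample_id": sample_id,
                    "culture_id": f"{sample_id}_F{c + 1:02d}",
                    "p41bb": min(p41bb, 100.0),
                    "p41bb_til_alone": bg41_alone,
                    "p41bb_til_apc": bg41_apc,
                    "ifng": ifng,
                    "ifng_til_alone": bgif_alone,
                    "ifng_til_apc": bgif_apc,
                }
            )
    return pd.DataFrame(rows)


def _random_cdr3(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 21))
        cdr3 = "".join(rng.choice(_AA_ALPHABET, size=length))
        if cdr3 not in existing:
            existing.add(cdr3)
            return cdr3


def simulate_repertoire(
    theta_j: float, config: CohortConfig, seed: int, sample_id: str = "S001"
) -> pd.DataFrame:
    """Clonotype table of one sample: richness scales with inflammation.

    The number of unique clonotypes interpolates the configured range by
    ``theta_j`` (with multiplicative noise), clone counts are geometric
    with parameter ``repertoire_decay``, and CDR3s are random valid
    amino-acid strings of length 8-20. TRA richness is drawn at ~80% of
    TRB richness, mirroring the typically lower alpha-chain recovery.
    """
    if not (0 <= theta_j <= 1):
        raise ValueError("theta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = config.repertoire_clones_range
    base = lo + theta_j * (hi - lo)
    rows = []
    seen: set[str] = set()
    for chain, scale in (("TRB", 1.0), ("TRA", 0.8)):
        richness = max(1, int(round(base * scale * rng.uniform(0.85, 1.15))))
        counts = rng.geometric(config.repertoire_decay, size=richness)
        for count in counts:
            rows.append(
                {
                    "sample_id": sample_id,
                    "chain": chain,
                    "cdr3_aa": _random_cdr3(rng, seen),
                    "count": int(count),
                }
            )
    return pd.DataFrame(rows)


def simulate_repertoires(truth: CohortTruth, config: CohortConfig) -> pd.DataFrame:
    """Clonotype tables for the whole cohort (one substream per sample)."""
    master = config.rng("repertoire")
    seeds = master.integers(0, 2**31 - 1, size=len(truth.theta))
    tables = [
        simulate_repertoire(float(t), config, int(s), sample_id=str(sid))
        for (sid, t), s in zip(truth.theta.items(), seeds)
    ]
    return pd.concat(tables, ignore_index=True)


def _sc_sample_ids(truth: CohortTruth, config: CohortConfig) -> list[str]:
    """Highest- and lowest-inflammation samples selected for single cell."""
    ordered = truth.theta.sort_values()
    k = config.n_sc_samples_per_group
    return list(ordered.index[-k:]) + list(ordered.index[:k])


def simulate_cells(
    config: CohortConfig, truth: CohortTruth, sample_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-structured single cells for selected samples.

    Returns (cells-by-genes count matrix, per-cell annotation frame with
    ``sample_id`` and ``true_bucket``), and records the true buckets in
    ``truth.cell_true_bucket``. Per sample the immune fraction rises with
    theta while the tumor fraction falls. Baseline counts are Poisson
    with per-gene rates; immune cells overexpress the planted immune
    program and PTPRC, tumor cells the melanoma markers, and stroma cells
    have exact zeros on all seven marker genes.
    """
    rng = config.rng("cells")
    universe, _, _ = _gene_universe(config)
    gene_index = pd.Index(universe)
    for marker in MARKER_GENES:
        if marker not in gene_index:
            raise ValueError(f"marker gene {marker} missing from the gene universe")
    if sample_ids is None:
        sample_ids = _sc_sample_ids(truth, config)

    marker_pos = {g: gene_index.get_loc(g) for g in MARKER_GENES}
    immune_cols = [gene_index.get_loc(g) for g in truth.immune_gene_ids]
    lam = rng.uniform(0.5, 4.0, config.n_genes)

    blocks = []
    meta_rows = []
    for sample_id in sample_ids:
        t = float(truth.theta.loc[sample_id])
        p_immune = 0.08 + 0.45 * t
        p_tumor = max(0.05, 0.85 - 0.50 * t)
        p_stroma = max(0.02, 1.0 - p_immune - p_tumor)
        probs = np.array([p_immune, p_tumor, p_stroma])
        probs /= probs.sum()
        buckets = rng.choice(["immune", "tumor", "stroma"], size=config.n_cells_per_sample, p=probs)
        counts = rng.poisson(lam[None, :], size=(config.n_cells_per_sample, config.n_genes))
        counts = counts.astype(np.int64)
        is_immune = buckets == "immune"
        is_tumor = buckets == "tumor"
        is_stroma = buckets == "stroma"
        # Marker structure: each bucket zeroes the other lineage's markers.
        counts[:, [marker_pos[g] for g in MARKER_GENES]] = 0
        counts[np.ix_(is_immune, [marker_pos[g] for g in IMMUNE_MARKERS])] = (
            1 + rng.poisson(20.0, size=(is_immune.sum(), len(IMMUNE_MARKERS)))
        )
        counts[np.ix_(is_tumor, [marker_pos[g] for g in TUMOR_MARKERS])] = (
            1 + rng.poisson(10.0, size=(is_tumor.sum(), len(TUMOR_MARKERS)))
        )
        # Immune cells also run the immune transcriptional program hotter.
        counts[np.ix_(is_immune, immune_cols)] += rng.poisson(
            2.0, size=(int(is_immune.sum()), len(immune_cols))
        )
        del is_stroma
        blocks.append(counts)
        for i, bucket in enumerate(buckets):
            meta_rows.append(
                {"cell_id": f"{sample_id}_C{i + 1:04d}", "sample_id": sample_id, "true_bucket": bucket}
            )

    matrix = pd.DataFrame(
        np.vstack(blocks), index=[r["cell_id"] for r in meta_rows], columns=universe
    )
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    truth.cell_true_bucket = meta["true_bucket"].copy()
    return matrix, meta


IMMUNE_FIXTURE_SET_NAMES = [
    "IFN_GAMMA_RESPONSE_LIKE",
    "IFN_ALPHA_RESPONSE_LIKE",
    "ALLOGRAFT_REJECTION_LIKE",
    "IL2_STAT5_SIGNALING_LIKE",
]


def build_fixture_genesets(truth: CohortTruth, config: CohortConfig) -> GeneSetCollection:
    """Hallmark-like fixture gene sets for the discovery stage.

    Immune/inflammatory sets sample the planted immune program; decoy
    sets mirror the decoy programs (metabolic/liver-like motifs); random
    sets draw from the unplanted background.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)).generate_state(1)[0])
    universe, immune, decoys = _gene_universe(config)
    collection = GeneSetCollection()
    size = min(40, len(immune))
    for name in IMMUNE_FIXTURE_SET_NAMES:
        genes = list(rng.choice(immune, size=size, replace=False))
        collection.add(GeneSet(name, up=genes, description="immune fixture"))
    decoy_names = ["METABOLISM_LIKE", "BILE_ACID_LIVER_LIKE", "CELL_CYCLE_LIKE", "WNT_SIGNALING_LIKE"]
    for k, program in enumerate(decoys):
        name = decoy_names[k % len(decoy_names)]
        if k >= len(decoy_names):
            name = f"{name}_{k}"
        collection.add(GeneSet(name, up=list(program), description="decoy fixture"))
    background = [g for g in universe if g.startswith("GENE")]
    for i in range(3):
        genes = list(rng.choice(background, size=min(40, len(background)), replace=False))
        collection.add(GeneSet(f"RANDOM_SET_{i + 1}", up=genes, description="random fixture"))
    return collection


def write_cohort(out_dir, config: CohortConfig) -> dict[str, object]:
    """Generate and persist a full synthetic cohort to ``out_dir``.

    Writes counts and gene-length TSVs, the fixture GMT, reactivity and
    clonotype TSVs, a covariates TSV (TMB), the single-cell matrix as an
    MTX triplet with barcode/feature lists plus true buckets, and the
    ground truth as JSON. Returns the in-memory objects for pipeline use.
    """
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts, truth = simulate_bulk_counts(config)
    reactivity = simulate_reactivity(truth.theta, config)
    clonotypes = simulate_repertoires(truth, config)
    cells, cell_meta = simulate_cells(config, truth)
    genesets = build_fixture_genesets(truth, config)

    counts.values.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    counts.gene_lengths.to_frame().to_csv(out / "gene_lengths.tsv", sep="\t", index_label="gene_id")
    reactivity.to_csv(out / "reactivity.tsv", sep="\t", index=False)
    clonotypes.to_csv(out / "clonotypes.tsv", sep="\t", index=False)
    truth.tmb.to_frame().to_csv(out / "covariates.tsv", sep="\t", index_label="sample_id")
    write_gmt(genesets, out / "genesets.gmt")

    cells_dir = out / "cells"
    cells_dir.mkdir(exist_ok=True)
    mmwrite(str(cells_dir / "matrix.mtx"), csr_matrix(cells.to_numpy()))
    (cells_dir / "barcodes.tsv").write_text("\n".join(cells.index) + "\n")
    (cells_dir / "features.tsv").write_text("\n".join(cells.columns) + "\n")
    cell_meta.to_csv(cells_dir / "cell_samples.tsv", sep="\t")

    truth_payload = {
        "theta": truth.theta.round(10).to_dict(),
        "immune_gene_ids": truth.immune_gene_ids,
        "decoy_gene_ids": truth.decoy_gene_ids,
        "true_reactive_fraction": truth.true_reactive_fraction.round(10).to_dict(),
        "tmb": truth.tmb.round(10).to_dict(),
        "cell_true_bucket": truth.cell_true_bucket.to_dict(),
        "config": asdict(config),
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))

    return {
        "counts": counts,
        "truth": truth,
        "reactivity": reactivity,
        "clonotypes": clonotypes,
        "cells": cells,
        "cell_meta": cell_meta,
        "genesets": genesets,
    }
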