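"""End-to-end orchestration with a config file and reproducibility manifest.

``run_all`` chains the stages in analysis order — simulate (or ingest)
-> normalize -> discover -> score -> reactivity / repertoire / single-cell
catalog -> benchmark — persisting each stage's outputs under the run
directory and summarizing them in a manifest with content digests, so a
rerun with the same config and seed reproduces the digests bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as catalog_mod
from . import reactivity as reactivity_mod
from . import repertoire as repertoire_mod
from .discovery import discover_signature
from .expression import (
    aggregate_duplicate_genes,
    compute_tpm,
    log_stabilize,
    normalize_by_size_factors,
    size_factors_median_of_ratios,
)
from .genesets import GeneSet, GeneSetCollection, write_gmt
from .scoring import dichotomize_by_median, umis
from .synthetic import CohortConfig, IMMUNE_FIXTURE_SET_NAMES, write_cohort

__all__ = ["StageError", "load_config", "run_all"]

_COHORT_FIELDS = {f.name for f in dataclasses.fields(CohortConfig)}

_DEFAULT_STAGE_OPTIONS = {
    "top_variance_fraction": 0.10,
    "n_geneset_clusters": 4,
    "immune_set_names": IMMUNE_FIXTURE_SET_NAMES,
    "reactive_threshold_pct": 33.0,
    "background_rule": "max",
    "ucell_r_max": 1500,
    "de_lfc_min": 0.5,
    "de_fdr_max": 0.05,
    "score_centered": False,
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> tuple[CohortConfig, dict]:
    """Split a YAML config into cohort settings and stage options."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    cohort_kwargs = {k: v for k, v in payload.items() if k in _COHORT_FIELDS}
    for key in ("baseline_log_mean_range", "repertoire_clones_range"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    options = dict(_DEFAULT_STAGE_OPTIONS)
    options.update({k: v for k, v in payload.items() if k not in _COHORT_FIELDS})
    return CohortConfig(**cohort_kwargs), options


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: CohortConfig | str | Path,
    out_dir,
    options: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline; returns (and writes) the run manifest."""
    if not isinstance(config, CohortConfig):
        config, loaded_options = load_config(config)
        merged = dict(loaded_options)
        merged.update(options or {})
        options = merged
    else:
        merged = dict(_DEFAULT_STAGE_OPTIONS)
        merged.update(options or {})
        options = merged
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {}

    stage = "simulate"
    try:
        data = write_cohort(out / "inputs", config)
    except Exception as exc:  # noqa: BLE001 - stage-named error surface
        raise StageError(stage, str(exc)) from exc

    stage = "normalize"
    try:
        counts = aggregate_duplicate_genes(data["counts"])
        size_factors = size_factors_median_of_ratios(counts)
        normalized = normalize_by_size_factors(counts, size_factors)
        log_matrix = log_stabilize(normalized)
        tpm = compute_tpm(counts)
        size_factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t", index_label="sample_id")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "discover"
    try:
        discovery = discover_signature(
            log_matrix,
            tpm,
            data["genesets"],
            immune_set_names=list(options["immune_set_names"]),
            top_fraction=float(options["top_variance_fraction"]),
            n_clusters=int(options["n_geneset_clusters"]),
        )
        signature_sets = GeneSetCollection()
        signature_sets.add(
            GeneSet("DISCOVERED_IMMUNE_SIGNATURE", up=discovery.signature.gene_ids)
        )
        write_gmt(signature_sets, out / "signature.gmt")
        (out / "signature_provenance.json").write_text(
            json.dumps(discovery.signature.provenance, indent=1)
        )
        discovery.correlations.rho.to_csv(out / "pc_geneset_rho.tsv", sep="\t")
        summary["immune_pc"] = discovery.immune_pc
        summary["immune_direction"] = discovery.immune_direction
        summary["n_signature_genes"] = len(discovery.signature)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "score"
    try:
        scores = umis(tpm, discovery.signature, centered=bool(options["score_centered"]))
        score_series = pd.Series({s.sample_id: s.score for s in scores}, name="umis")
        groups = dichotomize_by_median(score_series)
        pd.DataFrame({"umis": score_series, "group": groups}).to_csv(
            out / "scores.tsv", sep="\t", index_label="sample_id"
        )
        summary["umis_median"] = float(score_series.median())
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "reactivity"
    try:
        classified = reactivity_mod.classify_table(
            data["reactivity"], background_rule=str(options["background_rule"])
        )
        pct = reactivity_mod.percent_reactive(classified).reindex(score_series.index)
        pct.to_frame().to_csv(out / "percent_reactive.tsv", sep="\t", index_label="sample_id")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "benchmark"
    try:
        predictors = {"umis": score_series, "tmb": data["truth"].tmb}
        results = reactivity_mod.benchmark_predictors(
            predictors, pct, reactive_threshold=float(options["reactive_threshold_pct"])
        )
        bench = pd.DataFrame([dataclasses.asdict(r) for r in results])
        bench.to_csv(out / "benchmark.tsv", sep="\t", index=False)
        for r in results:
            summary[f"{r.predictor}_auc"] = r.auc
            summary[f"{r.predictor}_rho"] = r.spearman_rho
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "tcr"
    try:
        tabulated = repertoire_mod.tabulate_clonotypes(data["clonotypes"])
        metrics = repertoire_mod.repertoire_metrics(tabulated)
        metrics.to_csv(out / "repertoire_metrics.tsv", sep="\t", index=False)
        trb = metrics[(metrics["chain"] == "TRB") & (~metrics["excluded"])]
        merged_scores = score_series.reindex(trb["sample_id"])
        if len(trb) >= 3:
            rho, _ = reactivity_mod.spearman_predictor(
                merged_scores.to_numpy(), trb["shannon"].to_numpy()
            )
            summary["umis_trb_diversity_rho"] = rho
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "sc_catalog"
    try:
        buckets = catalog_mod.assign_buckets(data["cells"], r_max=int(options["ucell_r_max"]))
        annotations = data["cell_meta"].copy()
        annotations["bucket"] = buckets
        annotations.to_csv(out / "cell_annotations.tsv", sep="\t")
        accuracy = float((annotations["bucket"] == annotations["true_bucket"]).mean())
        summary["bucket_accuracy"] = accuracy
        proportions = catalog_mod.proportions_per_sample(annotations.reset_index())
        proportions.to_csv(out / "cell_proportions.tsv", sep="\t")
        sc_groups = groups.reindex(proportions.index)
        if (sc_groups == "high").sum() >= 2 and (sc_groups == "low").sum() >= 2:
            prop_results = catalog_mod.proportion_test(proportions, sc_groups)
            pd.DataFrame([dataclasses.asdict(r) for r in prop_results]).to_csv(
                out / "proportion_tests.tsv", sep="\t", index=False
            )
        cell_groups = sc_groups.reindex(annotations["sample_id"]).set_axis(annotations.index)
        immune_cells = annotations.index[annotations["bucket"] == "immune"]
        if len(immune_cells) >= 4 and cell_groups.loc[immune_cells].nunique() == 2:
            de = catalog_mod.wilcoxon_de(
                np.log2(data["cells"].loc[immune_cells] + 1.0),
                cell_groups.loc[immune_cells],
                lfc_min=float(options["de_lfc_min"]),
                fdr_max=float(options["de_fdr_max"]),
            )
            de.to_csv(out / "immune_de.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "manifest"
    try:
        outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
        manifest = {
            "config": dataclasses.asdict(config),
            "options": {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in options.items()},
            "seed": config.seed,
            "summary": summary,
            "outputs": {str(p.relative_to(out)): _digest(p) for p in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    return manifest
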