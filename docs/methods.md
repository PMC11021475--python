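# Methods

This note documents the models and procedures implemented in `umiskit`,
the parameters that matter, the synthetic cohort the tests run on, and
the design choices made where the design was genuinely open. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Bulk normalization

Raw gene-by-sample counts (duplicate gene ids summed, as arises from
many-to-one identifier conversion) are normalized two ways for two
purposes:

* **Cross-sample comparability** (PCA): median-of-ratios size factors —
  per gene, a geometric-mean reference over samples, restricted to genes
  with all-positive counts; per sample, the median count/reference ratio.
  This is the classic DESeq rule and agrees with `pydeseq2.deseq2_norm`
  to 1e-10 (asserted in the tests). The variance-stabilizing transform is
  log2(x+1) on the normalized counts. A dispersion-model-based transform
  would differ in the low-count tail, but every downstream consumer here
  (rank scoring, Spearman correlation) is invariant to monotone
  within-sample transforms, so the substitution does not propagate.
  One subtlety: re-estimating size factors after normalization returns a
  common constant (the geometric mean of the original factors), not
  exactly 1 — the rule recenters ratios at the median, which coincides
  with the geometric mean only for log-symmetric count distributions.
* **Within-sample abundance** (scoring): TPM — counts divided by gene
  length in kb, scaled so each sample sums to 1e6.

Top-variance gene selection takes the ceil(fraction × n_genes) genes with
the largest log-scale variance (default fraction 0.10), ties broken by
input order, computed over all retained genes (no prior zero-variance
filter).

## Signature discovery

PCA runs on samples-as-observations with genes centered and *not* scaled
to unit variance: the log transform already homogenizes scale, and
unit-variance scaling would let thousands of flat genes dilute the
planted covariance structure. Decomposition is a full SVD; orientation is
fixed deterministically (the largest-magnitude loading of each PC is
positive).

Candidate PCs for the immune-axis search are those explaining > 5%
variance, capped at 3 — in practice the leading components carry the
interpretable covariance programs while later PCs are noise-sized. Gene
sets are correlated with candidate PCs by Spearman's ρ (average-rank
ties; constant vectors recorded as missing), and the profiles are
clustered by complete-linkage hierarchical clustering on Euclidean
distance (the deterministic default of the heatmap tooling this procedure
mirrors), cut at k = 4.

The immune axis maximizes |mean ρ| over a named list of
immune/inflammatory sets (default: the interferon/allograft/IL2-like
fixture sets of the generator; user-overridable). Ties go to the lower
PC index. An exclusivity diagnostic (winner |mean ρ| / runner-up) is
reported so a non-exclusive axis is visible. Both the named-set mean and
post-clustering cluster means are available (`identify_immune_axis`
consumes any row subset of the correlation matrix).

Signature selection is the literal sign rule: every PCA-input gene whose
loading on the immune PC is strictly of the matching sign; zero loadings
are excluded, so positive-signature, negative-signature, and zero-loading
genes partition the PCA gene set. The selected count is recorded in the
signature's provenance.

## Single-sample scoring

**Singscore (unidirectional).** Genes are ranked ascending within one
sample (ties averaged); the score is the set's mean rank min–max
normalized by its theoretical extremes, giving [0, 1] uncentered. The
default reports uncentered scores; `centered=True` subtracts 0.5. Whether
a published score used centering cannot generally be read off its range,
so both variants are exposed and neither is privileged. Signature genes
absent from a sample's universe are dropped per sample with the used set
size logged — single-sample robustness to panel differences.

**Bidirectional.** The expected-down component applies the same formula
to reversed ranks; centered components sum to [−1, 1]. An empty down set
is rejected rather than silently reduced to unidirectional — the mode is
an explicit analysis choice.

**Capped-rank per-cell score.** Genes are ranked *descending* (the
opposite convention from singscore; both are fixed at the operation level
to prevent drift), ranks beyond r_max = 1500 are truncated to r_max + 1,
and the score is 1 − U/(n·r_max) with U the rank-sum statistic. A set
entirely beyond the cap is clamped to exactly 0: the raw formula would
leave a floor of (n−1)/(2·r_max), which would make the cataloging rule
"score > 0" vacuously true for every multi-gene set. The clamp makes
"> 0" mean "at least one signature gene inside the rank cap".

Median dichotomization puts strictly-above-median samples in the high
group; ties at the median go low.

## Reactivity classification and benchmarking

The dual-gate rule follows the assay's definition exactly: the absolute
gates (> 1% 4-1BB, > 100 pg/ml IFN-γ) are strict and the
twice-background comparisons inclusive (≥). The two control conditions
(TIL alone, TIL + autologous APCs) are combined by maximum by default —
the conservative choice; `sum` and `apc`-only rules are selectable since
assay reports rarely state the combination. Zero background leaves only
the absolute gate binding. The rule is monotone: raising a measurement
never flips reactive to not-reactive (property-tested).

ROC curves are computed directly over predictor thresholds, tied scores
grouped; AUC is the trapezoid rule, which equals the concordant-pair
fraction with ties counted ½ (asserted against brute-force pair counting
on all small instances). A univariate logistic fit would produce the
identical ROC because the logistic map is monotone in one predictor, so
the fit is omitted. Spearman p-values are FDR-adjusted (Benjamini–
Hochberg) across benchmarked predictors. The clinical response threshold
helper returns the median score of the nonresponder group.

## Repertoire metrics

Shannon diversity uses natural log (the convention of the repertoire
tools this follows; the base cancels in clonality regardless). Clonality
is 1 − H/ln S, undefined for S ≤ 1; such sample–chain pairs are excluded
and flagged rather than imputed. Clonotype identity is (chain, amino-acid
CDR3) only — V/J segments are ignored. AIRR-style column aliases
(`junction_aa`, `duplicate_count`, `locus`) are accepted; rows with
non-amino-acid CDR3 characters are rejected with a warning. A clonotype
is public when observed in ≥ 2 samples.

## Single-cell cataloging

Bucket precedence is immune → tumor → stroma, evaluated on the capped-
rank score: this mirrors the biological asymmetry that PTPRC (CD45)
expression identifies hematopoietic cells even when melanoma transcripts
are ambiently present. Granular immune phenotyping by reference-atlas
mapping is out of scope (the atlas is an external artifact); the bucket
rules are self-contained.

The composition test transforms per-sample proportions by arcsin(√p) and
applies an ordinary two-sample t-test per cell type with BH-FDR across
types. This is a propeller-style test without moderated variance; at the
3-vs-3 group sizes typical of single-cell designs, moderation is
material, so p-values are not claimed to match the moderated tool —
fold enrichment (mean-proportion ratio, high/low) is unaffected.
Differential expression is a per-gene two-sided Wilcoxon rank-sum test
with log2fc = log2((mean_high+1)/(mean_low+1)) (pseudocount 1 on
normalized expression; positive = higher in the high group), BH-FDR, and
the |log2fc| ≥ 0.5, FDR < 0.05 retention filter.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the study
conditions under which every end-to-end claim is made.

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 60 | metastases in the cohort |
| `n_genes` | 2000 | gene universe |
| `n_immune_genes` | 150 | planted immune program size |
| `n_decoy_programs` / `decoy_program_size` | 2 / 25 | metabolic/liver-like decoy covariance programs |
| `immune_effect` | 2.0 | log2 shift of immune means from θ=0 to θ=1 |
| `nb_dispersion` | 0.02 | NB dispersion α (var = μ + αμ²) |
| `baseline_log_mean_range` | (5, 9) | per-gene baseline log2 means |
| `n_cultures_per_sample` | 24 | TIL fragment cultures per metastasis |
| `reactivity_slope` / `intercept` | 6 / −3 | logistic link θ → P(culture reactive) |
| `repertoire_clones_range` | (5, 250) | TRB richness at θ=0 … θ=1 |
| `repertoire_decay` | 0.1 | geometric clone-size parameter |
| `n_cells_per_sample` | 500 | cells per single-cell sample |
| `n_sc_samples_per_group` | 3 | highest-/lowest-θ samples given cells |

A single integer seed drives named substreams (theta, bulk, reactivity,
repertoire, cells, covariates) via a seed-sequence hierarchy, so each
component regenerates independently and bit-identically. θ is uniform on
[0, 1]. Dispersion 0.02 and baseline means of 2⁵–2⁹ counts describe
well-expressed genes at ~50M-read depth; at these settings the planted
programs separate cleanly from background variance, which is what lets
the discovery stage act as a parameter-recovery test at n = 60. The TMB
covariate is log-normal around 0.64 mutations/Mb (the canonical low
uveal-melanoma burden) and independent of θ by construction — it is the
designed-null biomarker in the benchmark.

Reactive cultures receive assay values constructed above both gates and
above twice their simulated controls; non-reactive cultures stay below
the absolute gates, so the classifier recovers the latent reactivity
flags exactly and the percent-reactive outcome is binomial noise around
the logistic link. Single-cell samples are the 3 highest- and 3 lowest-θ
samples (mirroring a 3-high/3-low single-cell design); immune cells
express PTPRC (1 + Poisson(20)) and run the immune program hotter, tumor
cells express the six melanoma markers, stroma cells have exact zeros on
all seven markers, and baseline Poisson rates (0.5–4 per gene) keep cells
dense enough that all-zero marker sets fall beyond the rank cap.

What the generator does **not** emulate: raw reads/UMIs, doublets,
ambient RNA, batch effects, library-size gradients correlated with
biology, somatic mutations/CNVs (TMB is a bare covariate), cell-type
hierarchies below the three buckets, or realistic CDR3 sequence motifs
(CDR3s are uniform random amino-acid strings of length 8–20, so sharing
across synthetic samples is essentially absent). Passing tests therefore
demonstrate correctness and recoverability of the analysis machinery at
realistic effect sizes — not performance on real tumors, where effect
sizes, confounding, and panel composition differ.

## Numerical choices and degenerate inputs

* Ties: average ranks everywhere (scipy convention); variance-selection
  ties break by input gene order; equal |mean ρ| axis ties break to the
  lower PC index.
* Constant vectors: Spearman ρ is recorded as missing, never 0.
* All-zero TPM columns are zeroed with a warning; zero gene lengths are
  errors.
* Degenerate composition tests (a cell type absent everywhere) report
  NaN p with a warning rather than failing the whole analysis.
* Pipeline determinism is enforced by content digests in the run
  manifest; a rerun with the same config and seed reproduces every
  digest.

## Problem sizes

The test suite and the acceptance script run the full default cohort
(60 samples × 2000 genes, 1440 cultures, ~15k clonotypes, 3000 cells);
oracle-equivalence suites use 100 random instances of N ≤ 50 and ROC
instances of n ≤ 20. The whole suite completes in well under a minute on
one CPU; these sizes were chosen because every asserted effect is already
stable across seeds at this scale.

## Known limitations

* The published signature (2394 genes) and score range (0.114–0.347,
  median 0.237) belong to the restricted-access patient cohort and are
  not reproduced here; the discovery procedure is validated by parameter
  recovery on synthetic data instead.
* Whether published scores were centered, and how the two assay controls
  were combined, are not derivable from public descriptions; both choices
  are exposed as options with documented defaults.
* The composition test's unmoderated variance makes its p-values
  anti-conservative relative to moderated alternatives at very small
  group sizes.
* `select_response_threshold` and `diversity_delta` support outcome
  analyses whose survival-curve components are deliberately out of scope.
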