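# umiskit

Immunogenomic profiling of tumor metastases from bulk and single-cell
transcriptomics, built around the analysis that produced the Uveal
Melanoma Immunogenomic Score (UMIS): a single-sample, rank-based
enrichment score of an unsupervised immune/inflammatory gene signature
that predicts whether a metastasis harbors tumor-reactive
tumor-infiltrating lymphocytes (TIL).

The package is aimed at computational immuno-oncologists who want the
full analysis chain as tested, reusable components: signature discovery,
single-sample scoring, TIL-reactivity benchmarking, TCR repertoire
metrics, and single-cell cataloging — exercised end-to-end on a seeded
synthetic cohort generator, because the original patient data are under
restricted access.

## The method

**Discovery.** Bulk counts are normalized with median-of-ratios size
factors, log2(x+1)-stabilized, and restricted to the 10% most variant
genes. PCA (genes centered, no scaling) yields sample coordinates; each
hallmark-style gene set is scored per sample with the unidirectional
singscore, and Spearman's ρ between set enrichment and each leading PC is
clustered (complete linkage, Euclidean distance) into biologic motifs.
The immune axis is the PC whose mean ρ over the named immune/inflammatory
sets has the largest magnitude; the signature is every PCA-input gene
whose loading sign on that PC matches the immune direction — no
supervised filtering.

**Scoring.** For a sample with *N* genes and a signature of *n* genes at
mean ascending rank *m̄*, the singscore is

    score = (m̄ − (n+1)/2) / ((2N−n+1)/2 − (n+1)/2)  ∈ [0, 1]

computed on TPM within one sample at a time, so it is invariant to any
monotone within-sample transform and needs no cohort context. A
bidirectional mode adds an expected-down component on reversed ranks.
Samples are split into high/low groups at the cohort median score.

**TIL reactivity.** A TIL culture is tumor-reactive when 4-1BB⁺ CD3⁺
cells exceed 1% *and* at least twice background, or IFN-γ exceeds
100 pg/ml *and* at least twice background (background = max of the
TIL-alone and TIL+APC controls). The per-metastasis outcome is
100 × reactive/total cultures; biomarkers are benchmarked by Spearman ρ
against that percentage and by trapezoid-rule ROC AUC for predicting
≥ 33% reactive cultures.

**Repertoire.** Clonotypes are (chain, amino-acid CDR3) pairs. Per sample
and chain: Shannon diversity H = −Σ pᵢ ln pᵢ and clonality = 1 − H/ln S;
samples with ≤ 1 unique clonotype are excluded (clonality undefined).

**Single cells.** Cells are bucketed with a capped-rank Mann–Whitney
U score (descending ranks truncated at r_max = 1500): immune if the PTPRC
score is > 0, else tumor if the melanoma-marker score (SOX10, S100A1,
MITF, MLANA, PMEL, TYR) is > 0, else stroma. Composition differences use
a t-test on arcsin-√ proportions with mean-ratio fold enrichment;
differential expression uses the Wilcoxon rank-sum test filtered at
|log2fc| ≥ 0.5 and FDR < 0.05.

## Worked example

Create `demo.yaml`:

```yaml
n_samples: 60
n_genes: 2000
n_immune_genes: 150
seed: 1
```

and run the pipeline:

```sh
umis run --config demo.yaml --out demo_run
```

which simulates a 60-sample cohort (latent inflammation level θ per
sample driving a 150-gene immune program), runs discovery, scoring, and
all downstream stages, writes every table plus a digest manifest under
`demo_run/`, and prints:

```json
{
 "bucket_accuracy": 1.0,
 "immune_direction": "positive",
 "immune_pc": 1,
 "n_signature_genes": 151,
 "tmb_auc": 0.4973544973544973,
 "tmb_rho": -0.06388490983576757,
 "umis_auc": 0.996031746031746,
 "umis_median": 0.6481452297465249,
 "umis_rho": 0.962709324682316,
 "umis_trb_diversity_rho": 0.9599333148096695
}
```

Reading this: discovery located the planted immune program on PC1 and
selected a 151-gene signature; the per-sample score predicts ≥ 33%
reactive TIL cultures at AUC 0.996 and correlates with the percentage at
ρ 0.96, while the uninformative mutational-burden covariate sits at
chance (AUC 0.50); the score also tracks TRB repertoire diversity
(ρ 0.96), and single-cell bucket assignment recovers every true label.
Individual stages are available as `umis simulate`, `umis normalize`,
`umis discover`, `umis score`, `umis reactivity`, `umis benchmark`,
`umis tcr`, and `umis sc-catalog`; the same functionality is importable
from `umiskit`.

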