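# escctme

Analysis toolkit for dissecting neoadjuvant-therapy resistance in the
tumor microenvironment from paired single-cell RNA/TCR sequencing and
clinical follow-up, built around multi-patient, multi-tissue,
two-timepoint (pre-/post-treatment), two-response-group (MPR / NMPR)
cohort designs such as those used in locally advanced esophageal squamous
cell carcinoma (ESCC) trials.

It is written for computational biologists who have cell-level count
matrices with cluster annotations, 10x-style TCR contig tables, and
per-patient survival records, and who want the bespoke statistics of this
study design as tested, reusable functions rather than notebook code.

## What it computes

- **QC and normalization** — cells kept when the detected-gene count lies
  strictly in (300, 8000) and the mitochondrial fraction is below 20%
  (all configurable); library-size normalization
  `x → ln(1 + 10⁴·x/total)`.
- **Differential expression and signatures** — two-sided Wilcoxon
  rank-sum on normalized expression with Seurat-style `min.pct` /
  `logfc.threshold` pre-filters and Bonferroni correction (exact
  enumeration of the rank-sum null for groups of ≤ 8 cells); cell-state
  signatures as the top-40 up-regulated genes.
- **Signature scoring** — per-cell module scores (signature mean minus
  expression-bin-matched control mean), single-sample rank (ssGSEA-style)
  scores for bulk cohorts, and preranked GSEA (ES/NES with a
  gene-set-resampling null).
- **Ro/e tissue enrichment** — observed over chi-square-expected cell
  counts per (cell subtype, tissue × response) combination; Ro/e > 1
  flags preference. Raw Pearson chi-square tests on the same tables.
- **TCR repertoire** — paired-chain clonotype calling from contig CSVs,
  clone-size expansion classes (n > 2 vs n ≤ 2), the entropy-based
  expansion index `1 − H/ln C`, cross-phenotype clonotype overlap, and
  TCR_Alive / TCR_Dead clone-fate classification: a baseline-persisting
  clone is Alive when its post-treatment cell share exceeds 0.3
  (sensitivity grid 0.4/0.5/0.6), with a chi-square test of fate against
  response.
- **Ligand-receptor interactions** — mean-product scores between sender
  and receiver clusters with a one-sided label-permutation test,
  significant-pair counting, and a cell-fraction-adjusted cohort score
  for bulk data (e.g. CD47–SIRPA).
- **Survival** — Kaplan-Meier curves, log-rank tests, two-group Cox
  hazard ratios (Breslow ties), and score dichotomization at the median
  or a maximally selected log-rank cutpoint; EFS/OS endpoint
  constructors.
- **Synthetic cohorts** — a seeded generator producing the full data
  structure above (negative-binomial counts with planted enrichments and
  ligand-receptor coexpression, power-law TCR repertoires with
  response-dependent persistence, exponential survival) so every stage is
  testable without any data download.

## Worked example

```python
import warnings
from escctme.synthetic import CohortConfig, generate_cohort
from escctme.pipeline import PipelineConfig, run_pipeline
from escctme.preprocess import QCParams
from escctme.interactions import LRPair

bundle, contigs, tcr_meta, surv, truth = generate_cohort(
    CohortConfig(cells_per_sample=60, n_genes=200, rng_seed=1)
)
cfg = PipelineConfig(
    qc=QCParams(min_genes=10, max_genes=8000),
    lr_pairs=(LRPair("IL1A_IL1R2", "IL1A", "IL1R2"),),
    lr_sender="Epi_PRDM1", lr_receiver="Treg", n_perm=199,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_pipeline(cfg, bundle=bundle, contigs=contigs,
                          tcr_meta=tcr_meta, survival_table=surv)
print(report.stages["roe"]["table"]["PostT-NMPR"]["Treg"])
print(report.stages["repertoire"]["clone_fates"])
print(report.stages["interactions"]["results"][0])
```

prints

```
2.0135
{'TCR_Dead': 310, 'TCR_Alive': 230}
{'pair': 'IL1A_IL1R2', 'score': 27.84535381189351, 'p_value': 0.005}
```

The Ro/e of 2.01 recovers the planted 3-fold regulatory-T-cell enrichment
in post-treatment non-responder tissue (the value is below 3 because the
planted condition itself inflates the cohort-wide Treg margin); 230 of
540 baseline-persisting clones are TCR_Alive at the 0.3 threshold; and
the planted IL1A–IL1R2 coexpression between the malignant-cell sender and
Treg receiver is significant at p = 0.005 with 199 permutations.

A console script mirrors this flow: `escctme simulate --out dir --seed 1`,
`escctme run --input-dir dir`, `escctme validate dir`.

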