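# Methods

This note records the statistical conventions, defaults and design
choices behind each stage, what the synthetic cohort generator does and
does not emulate, and the known limitations.

## Quality control and normalization

A cell is retained when its detected-gene count `g` satisfies
`min_genes < g < max_genes` (strict inequalities; defaults 300 and 8000)
and its mitochondrial read fraction is strictly below `max_mito`
(default 0.20). Mitochondrial genes are recognized by a configurable
symbol prefix (`MT-`). Missing per-cell metrics are computed from the
count matrix; genes are never removed, and filtering is idempotent.
Removing every cell raises an explicit `EmptyResultWarning` rather than
returning a silent empty matrix.

Normalization is library-size correction to a fixed scale factor `s`
(default 10,000 — the Seurat convention; only the function, not the
constant, is fixed by the upstream workflow) followed by a log
transform: `y = ln(1 + s·x/total)`. Per cell, `Σ expm1(y)` equals `s` to
1e-8 relative tolerance, which the tests assert.

## Differential expression

Two-sided Wilcoxon rank-sum on normalized values between two disjoint
cell masks. A gene is tested only if `max(pct_in, pct_out) ≥ min_pct`
and `|log2FC| ≥ logfc_threshold`, where the fold change compares
`expm1`-means with a pseudocount of 1:
`log2FC = log2((mean(expm1 y_in) + 1) / (mean(expm1 y_out) + 1))`.
Base 2 is the package convention; the base is not identifiable from the
upstream tooling's description and is parameterized only through the
threshold scale. When both groups have ≤ 8 cells the p-value comes from
exact enumeration of all rank-sum assignments (midranks handle ties);
larger groups use the tie-corrected normal approximation without
continuity correction. Multiple testing is Bonferroni over the genes
actually tested. Signatures are the top-`n` (default 40) genes by
positive log2FC, ties broken by smaller p then gene id; short sets are
flagged rather than padded.

## Signature scoring

*Module score* (per cell): genes are ranked by mean normalized
expression and cut into `n_bins` equal-frequency bins (default 24,
matching the AddModuleScore defaults); each signature gene draws
`n_ctrl` (default 100) control genes with replacement from its bin using
a seeded generator; the score is the signature mean minus the pooled
control mean. Scores are exactly zero on constant matrices, invariant to
adding a constant, and bit-reproducible given (data, params, seed).

*Bulk rank score* (per sample): a weighted Kolmogorov-Smirnov running
sum over the sample's expression ranking — hits weighted by
`rank^alpha` (alpha 0.25, rank counted from the bottom so top genes
weigh most), misses uniform — averaged over positions and therefore
comparable across samples sharing a gene universe. This is an
ssGSEA-style statistic chosen over full GSVA kernel-CDF estimation: it
preserves the monotone intent (samples richer in the signature score
higher) without attempting numerical agreement with GSVA, which the
package does not claim. Constant samples score 0 and are flagged.

*Preranked GSEA*: ES is the signed maximum deviation of the weighted
hit CDF minus the miss CDF. The null resamples random gene sets of equal
size from the ranking (gene-set resampling rather than phenotype
permutation, because the intended contrasts are single-cell cluster
rankings where phenotype permutation is ill-defined). NES divides ES by
the mean |null ES| of matching sign. The one-sided p-value is the
add-one estimator against the same-sign null tail,
`p = (1 + #{|null| ≥ |ES|, same sign}) / (1 + #same-sign)`; conditioning
on the sign is what keeps null p-values uniform for a signed statistic,
a property the test suite checks with a KS test over 500 runs.

## Ro/e enrichment

For a cluster × condition contingency table, `Ro/e[i,j] = O[i,j]/E[i,j]`
with `E = rowsum·colsum/N` (the chi-square independence expectation).
Values above 1 indicate preference. The column-sum-weighted mean of each
row is exactly 1, expectations reproduce both margins exactly, and Ro/e
is invariant to scaling all counts — all asserted as properties. The
companion chi-square test is the raw Pearson statistic without Yates
correction (switchable), warning when any expected count is below 5.
Columns may be tissues alone or tissue × response crossed; crossed is
the default layout. Empty rows raise by default; `on_empty="na"` yields
NaN instead.

## TCR repertoire

Clonotypes require at least one productive, full-length TRA *and* TRB
per cell; with multiple chains of one type the highest-UMI contig wins
(UMI ties break to the lexicographically smaller CDR3, for
determinism). Identity defaults to nucleotide CDR3 pairs (the stricter
10x convention) with an amino-acid mode available. Clone sizes are
always computed within patient — TCR sharing across individuals is
biologically exceptional, so clones are never merged across patients.

Expansion classes report the fraction of cells (not clones) in clones of
size > 2 versus ≤ 2 per group. The expansion index is `1 − H/ln C`
(Shannon entropy in nats over clonotype frequencies; 0 for a maximally
even repertoire, 1 for monoclonal, NaN below 2 cells).

Clone fate: within patient, `ratio = n_post/(n_pre + n_post)`; a clone
is TCR_Alive when the ratio exceeds the threshold (default 0.3),
TCR_Dead otherwise; clones with no baseline cells are excluded by
default because the analysis tracks clones persisting from baseline. A
frequency-normalized ratio (compartment sizes divided out) is available
behind a flag, since the defining phrase admits both readings; raw
counts are the default. The sensitivity grid (0.4/0.5/0.6) re-runs the
classification; Alive sets are nested decreasing in the threshold. The
fate × response association is a Pearson chi-square on cell counts.

## Ligand-receptor interactions

The score for pair (L, R) from sender cluster S to receiver cluster T is
`mean(y_L | S) × mean(y_R | T)` on normalized expression. This
mean-product form with a label-permutation null replaces mass-action
communication models: the downstream claims rest only on the ranking and
significance of pairs, and the permutation test is the inferential
device of record. The null shuffles cluster labels over all cells
(sizes preserved), and `p = (1 + #{null ≥ observed})/(1 + n_perm)` —
one-sided by construction (scores are non-negative means), never zero,
with granularity `1/(n_perm+1)`, and bit-reproducible given the seed.

The cohort-level adjusted score for bulk data multiplies per-sample
ligand and receptor expression by min-max-rescaled single-sample
signature scores standing in for the sender and receiver cell fractions.
The fractions are computed on the matrix with the pair's own genes
removed, making the score monotone in ligand/receptor expression. This
surrogate is a declared convention, not a reconstruction of any
particular published normalization.

## Survival

Kaplan-Meier estimation, log-rank testing and the confidence bands
(log(−log) / exponential Greenwood transform) are delegated to
lifelines behind the module's interface; ties at one time are handled
events-first. The two-group Cox model is implemented directly:
Newton-Raphson on the Breslow-ties partial likelihood (the simplest
correct tie convention), Wald CI and p. When either group has zero
events the likelihood is monotone and a divergence flag is returned
instead of a number; the test suite cross-checks the estimator against
both a grid-search of the partial likelihood and lifelines'
`CoxPHFitter` on tie-free data.

Dichotomization: `median` puts subjects strictly above the median score
in the "high" group; `best` scans candidate cutpoints leaving at least
`min_prop` (default 0.1, the survminer default) of subjects on each side
and picks the one maximizing the absolute standardized log-rank
statistic, ties to the lower cutpoint. The reported p-value at the
chosen cut is the naive log-rank p, explicitly labeled uncorrected — no
correction for having searched cutpoints is applied. Under exponential
event-time noise the selected cutpoint localizes the true boundary only
to within a few ranks (neighboring cutpoints differ by single
observations), which is how the recovery test is framed.

EFS takes the first of progression, recurrence, metastasis or death,
censoring at last follow-up; OS counts death from any cause, censoring
survivors at the data cutoff.

## Synthetic cohort generator

The generator is the package's test bed and defines the conditions the
tests assert under. Defaults mirror the target study design: 9 patients
(5 MPR, 4 NMPR), 26 samples — Normal ×4, Adjacent ×5, pre-treatment
tumor ×9, post-treatment tumor ×8 (one NMPR patient lacks the
post-treatment sample) — at reduced scale for desk runtime (250 cells
per sample and 600 genes by default; tests use smaller). Counts are
negative binomial parameterized by (mean, dispersion 0.5) via a
Gamma-Poisson mixture, with log-normal gene baselines and per-cell
library factors — the standard scRNA-seq noise model, documented here
because the analysis itself assumes none. Clusters get 10 marker genes
at 8-fold (2³) mean shift; a 3-fold Treg proportion enrichment is
planted in NMPR post-treatment samples; IL1A→IL1R2 (malignant→Treg) and
CD47→SIRPA (malignant→macrophage) coexpression is planted at 8-fold.

TCR repertoires: 60 baseline clones per patient with power-law sizes
(exponent 2, truncated at 30); each clone persists after treatment with
probability 0.6 (MPR) versus 0.2 (NMPR), and persisting clones draw a
zero-truncated Poisson post-treatment size proportional to baseline —
giving direct control of the TCR_Alive fraction per response group.
Survival times are exponential per group with administrative censoring.
All outputs are byte-identical given the seed.

What the generator does **not** emulate: batch effects, doublets,
ambient RNA, cell-cycle structure, spatial organization, realistic gene-
gene correlation, or V/D/J segment usage. Passing recovery tests
therefore demonstrate that the estimators detect their target effects
under the stated noise model at the stated sizes — not robustness to
artifacts of real droplet data.

## Numerical conventions

Seeded `numpy.random.default_rng` everywhere; every stochastic output is
reproducible from (data, params, seed). Exact rank-sum enumeration below
the 8-per-group cutoff; tie-corrected normal approximation above.
Add-one permutation p-values avoid zero. Equal-frequency expression bins
with stable-rank tie-breaking. Clonotype ids are truncated SHA-1 digests
of the CDR3 pair, stable across processes. QC boundaries are strict
inequalities. Degenerate inputs (zero-total cells, constant score
vectors, single-row tables, missing genes) raise typed errors naming the
offender rather than coercing.

## Limitations

Cluster labels are an input: no graph clustering, integration, doublet
removal, copy-number inference or trajectory analysis is included. The
bulk rank score is ordinal, not numerically comparable to GSVA. The
maximally selected cutpoint's p-value is uncorrected. Multi-subunit
receptor complexes and pathway-level aggregation of ligand-receptor
pairs are out of scope, as are HDF5 persistence and alignment-level
processing.
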