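# Methods

This note records the models, parameter choices and numerical
conventions behind `gdtx`, and what the synthetic-data validation does
and does not establish about real data.

## QC filters and normalization

A gene is removed when its detection count (cells with count ≥ 1; the
detection threshold is a parameter) falls below
`max(min_cell_frac · n_cells, min_cells)` with defaults 0.2% and 10.
Reading the two bounds as "below either" — i.e. below the maximum — is
the only interpretation under which both numbers can bind (the fraction
rule for large cohorts, the absolute floor for small ones); the removal
report records which rule fired. A cell is removed when
`mito/total > max_mito_frac` (default 2%), mitochondrial genes being
recognised purely by an ID prefix (default `MT-`) since no fixed gene
list is assumed; zero-total cells are removed unconditionally and
reported separately. The default stage order is genes-then-cells;
`run_qc(..., genes_first=False)` swaps it, and both orders are verified
against brute-force recomputation. Normalization is
`log(1 + count · scale_total / cell_total)` with `scale_total = 10⁴`;
zeros stay zero and sparsity is preserved.

## Marker extraction

Markers come from a per-gene two-sided Wilcoxon rank-sum test of the
target cluster against the pooled background clusters on log-normalized
values, BH-adjusted over tested genes. A hurdle-model contrast would
treat detection and expression separately; the rank-sum contrast was
chosen because the signatures are consumed downstream only as
(gene, logFC) lists, and it is assumption-light and exactly testable
(null p-values are verified uniform in the suite). The effect size is
`log_fc = log(mean_t + ε) − log(mean_b + ε)` with ε = 10⁻⁹ guarding
log(0); genes constant across both groups are reported with
`log_fc = 0, p = 1`. Signature thresholds default to `q ≤ 0.05`,
`|log_fc| ≥ 0.25` (common practice for this kind of contrast; both are
exposed), each side truncated to `max_genes` by |log_fc| with ties
broken by gene ID for determinism.

## Clustering-robustness statistics

The adjusted Rand index is the standard permutation-model form
(delegated to scikit-learn; the test suite checks it exhaustively
against an independent pair-counting computation on all small
partitions). Subsample consistency draws cells without replacement and
assigns each sampled cell to the nearest original-cluster centroid
(Euclidean on normalized values). The cell's own cluster centroid is
computed leave-one-out: without that correction each cell's own
contribution to its centroid inflates agreement well above chance even
for completely unstructured data, which would make the statistic
uninterpretable as a robustness measure. With the correction,
well-separated simulated clusters give accuracy ≥ 0.99 and
fold-change-1 (structure-free) simulations give chance level.

## Per-cell enrichment scoring

Expression is first min-max normalized per gene across cells (constant
genes map to 0 — they carry no between-cell information). The signature
score is the equal-weight form `mean(up) − mean(down)`, computed as two
separate means rather than one signed mean; this matches the intended
sign semantics (positive ⇔ up genes expressed, down genes not) and
bounds the score in [−1, 1] on min-max data regardless of how unbalanced
the two sides are. Signature genes absent from the matrix are dropped
with a warning, not imputed. Positivity thresholds: 0 for up/down
signatures (the natural boundary of the sign semantics); for curated
sets, whose scores have no natural zero, a quantile rule (default 0.75)
or an exact 1-D two-means split — implemented by enumerating split
points on the sorted scores to minimise within-cluster SSE, which is
deterministic and has no k-means initialisation randomness; boundary
ties go to the lower cluster.

## TR segment annotation

Aligner-based workflows keep only uniquely mapping reads (high MAPQ) to
avoid mis-assigning reads among TR segments that share long identical
stretches. `gdtx` realises the same contract deterministically with
diagnostic k-mers: the index stores every k-mer of every segment in
canonical (lexicographically smaller strand) form, so lookups are
strand-symmetric by construction; a k-mer present in exactly one segment
is diagnostic for it. Defaults k = 21 (long enough to be specific,
shorter than any V/C segment) and min_diag = 3 (three independent
diagnostic k-mers ≈ 23 bp of segment-specific sequence under the
k-mer-overlap structure of a 90 bp read). A read with diagnostic hits to
two or more segments is AMBIGUOUS; with none, or with fewer than
min_diag hits to its single candidate, it is UNMAPPED — an
insufficient-evidence outcome, deliberately not counted as ambiguous.
`screen_unambiguous_segments` asks a stronger, read-independent
question: a segment is identifiable at a given read length iff *every*
window of that length contains ≥ min_diag diagnostic k-mers, so every
possible error-free read would be assigned. Positivity is called on
distinct UMIs (reads sharing a UMI are one molecule), with
min_reads = 1 by default; the threshold is exposed because the right
value depends on sequencing depth.

## Synthetic data

`simulate_counts` draws counts gene-wise from a gamma-Poisson (negative
binomial, `var = μ + αμ²`) with a single dispersion scalar α — droplet
data are overdispersed, and one scalar keeps the design interpretable.
Gene baseline means are lognormal(0, 1) normalised to a mean library of
`library_size_mean` (default 2,000 counts, a typical sorted-lymphocyte
depth); per-cell library factors are lognormal with σ = 0.3 and unit
mean; each cluster's markers (10 per cluster by default) have their mean
multiplied by `marker_fold_change` (default 4, a clear but not
caricatural subtype difference) in that cluster only. A small `MT-`
block (~1% of counts) exercises the mito filter. Defaults: 3 clusters ×
100 cells × 300 genes — large enough for the rank-sum contrast to have
power, small enough that the full suite runs in about a minute.

`simulate_vdj_reads` emits per-cell reads from segment references under
per-cluster Bernoulli positivity, uniform start positions, random
strand, and per-base substitution errors; a planted shared block between
two segments (`make_synthetic_segments`, a synthetic stand-in for a real
TR reference bundle) provides ground-truth ambiguity. Because positivity
is independent per segment, a cell may truly carry several segments; the
truth table therefore maps barcode → tuple of segments.

`simulate_bulk_cohort` gives each sample a latent score z ~ N(0, 1)
expressed through the signature genes (baseline 10, shift ±z by weight
sign, Gaussian noise σ = 0.5 — chosen so a ~20-gene signature recovers z
with r > 0.9, i.e. the score is informative but not noiseless). Survival
is exponential with hazard `h0 · exp(β z)` (h0 = 10⁻³ per day, median
~700 days, a plausible oncology cohort scale), censoring independent
exponential (default rate 3 × 10⁻⁴, ~25% censoring). Purity defaults to
uniform on [0.6, 0.7] — the generator emulates the post-filter analysis
cohort — and `decoy_sigs` adds signatures expressed through independent
latent scores with no hazard effect, for specificity experiments.

What the generators do **not** emulate: batch effects, doublets, ambient
RNA, gene–gene correlation beyond the planted markers, splice structure
in reads, non-proportional hazards, or covariate-dependent censoring.
Passing tests therefore demonstrate correctness of the computations and
calibration under the stated models, not robustness to those real-data
phenomena.

## Survival analysis

The purity window is the closed interval [0.6, 0.7] (boundaries
included; both ends are parameters). The signature score is
`Σ w_g x_gs / Σ |w_g|` over present signature genes with signed logFC
weights; by default expression is z-scored per gene across the cohort
first, since otherwise the "weighted average" is dominated by whichever
gene is most highly expressed — the flag `standardize=False` restores
the raw behaviour. Tertiles are ⌊n/3⌋ samples at each extreme (191
samples → 63 + 63), sorted by score with ties broken by sample ID so the
split is deterministic; the middle third is discarded. The Kaplan–Meier
estimator and the unweighted 1-df log-rank test are implemented directly
(product-limit recursion; hypergeometric variance at pooled event times)
and validated in the suite against an independent reference
implementation to 10⁻¹² and against a permutation null. Events tied
with censorings at the same time follow the usual convention: the
censored observations are still at risk at that time.

## Problem sizes used in validation

The acceptance script and test suite use: 50 random tied/censored
fixtures (n = 30 per arm) for the survival-core oracle with 2,000
permutations each; 400 null cohorts (n = 300) for type-I calibration;
100 cohorts (n = 300, β = −0.8, two decoy signatures) for recovery; 50
planted-cluster simulations (300 cells) for signature specificity; 300
cells at 60% positivity for VDJ recovery; 100 random fixtures for the
QC oracle. These sizes give stable Monte-Carlo estimates while keeping
the full validation under a minute of compute per block.

## Known limitations

* Cluster labels, cell-cycle phases and tumour purity are inputs; the
  package neither clusters nor infers them.
* The rank-sum marker contrast ignores the detection/expression split a
  hurdle model captures; logFC values are comparable within a run, not
  across normalization schemes.
* The k-mer uniqueness criterion is a deterministic proxy for MAPQ-based
  unique alignment; it does not model indels or gapped placements.
* The log-rank test is unweighted and univariate; no proportional-hazards
  modelling or covariate adjustment is provided.
* Gene identifiers are opaque case-sensitive strings; no alias or
  ID-system mapping is attempted.
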