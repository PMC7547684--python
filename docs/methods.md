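# Methods

## Coordinate conventions and promoter geometry

All coordinates are 0-based half-open; GTF input (1-based inclusive)
is converted on read, BED passes through. The TSS is `start` for `+`
genes and `end − 1` for `−` genes. TSS-relative offsets are signed in
the transcription direction (negative = upstream). The promoter is the
offset window `[−upstream, +downstream)` with the TSS as the first
downstream base, identically on both strands; defaults are
upstream = 1500 bp, downstream = 500 bp, the common CpG-island-promoter
convention, and both are configurable because no single window is
canonical. A methylation site falling inside two promoters contributes
to both genes — no distance tie-break — which slightly double-counts
shared regulatory regions but never silently drops signal.

## The differential-methylation screen

Site-level betas are collapsed to per-gene promoter means with
pairwise-complete handling of missing values (a gene needs at least
one non-missing site per sample to appear). The tumor/normal shift is
tested per gene with a two-sided Mann–Whitney U rather than a t-test:
beta values are bounded and often skewed near 0 or 1, where rank tests
keep their level. Degenerate genes with identical values in both
groups are reported with p = 1; groups with fewer than two samples
yield missing p and q. The methylation fold change uses
log2((β̄_T + ε)/(β̄_N + ε)) with ε = 0.01 to keep near-zero promoter
means from exploding the ratio. Benjamini–Hochberg correction is
applied within each cancer type separately, since types are screened
and reported per-cancer.

Classification thresholds default to Δβ ≥ 0.1, |log2FC| ≥ 0.585
(1.5-fold) and q ≤ 0.05 on both arms. The categories are concordance
categories by construction: a hypermethylated gene whose expression
rises is "unaltered", not "silenced", because the screen is looking
for methylation-driven expression change, not methylation change per
se. Swapping the tumor/normal labels maps silenced ↔ activated
exactly; this symmetry is tested.

Ranking of recurrent hits orders by (number of types silenced,
mean methylation log2FC, gene id) — the last key makes output
deterministic under full ties.

The TSS meta-profile pools per-site Δβ into fixed 100-bp offset bins
over ±3 kb. Bins with no sites are reported as NaN with count 0 rather
than interpolated. The peak-locating helper ignores empty bins.

## Cell-line concordance

Promoter beta versus expression across cell lines is summarized per
gene by Spearman correlation: the silencing relation is monotone but
has no reason to be linear, and Spearman is insensitive to the
log-scale choice for expression. A gene is confirmed at ρ ≤ −0.3,
p ≤ 0.05 and ≥ 5 complete line pairs (all configurable). Constant
vectors and short inputs yield a missing ρ and an unconfirmed record
instead of an error, so screening loops never stop on degenerate
genes.

## Clinical statistics

2^−ΔΔCt is implemented exactly as the textbook double normalization;
it is 1 whenever the sample and calibrator ΔCt agree and is invariant
to common Ct shifts (both are contract-tested). Paired t-tests handle
the two degenerate limits explicitly: all-zero differences give
(t = 0, p = 1), constant non-zero differences give a signed infinite t
with p reported as 0. Independent comparisons default to the Welch
form; pooled variance is available by flag.

Median dichotomization sends ties to the low group — deterministic,
and on an even number of distinct values it yields an exact half/half
split. Contingency association uses the Pearson chi-square **without**
continuity correction as the default: this is the convention under
which the published 44-patient clinicopathological table reproduces to
three decimals (e.g. T stage 0.0007 → 0.001, clinical stage
0.0017 → 0.002, smoking 0.0260); Yates-corrected and Fisher-exact
variants sit behind a flag. The 4×2 tumor-location association is
computed as an ordinary chi-square with df = 3; its published value
(0.092) is not reproducible by Pearson chi-square and was likely an
exact test, so it is reported with that caveat and not treated as a
reference value.

A note on permutation checks: permuting patient labels in a 2×2 table
realizes the exact conditional (hypergeometric) distribution of the
chi-square statistic, whose discrete tail p differs from the
asymptotic chi-square p by up to several percent at n ≈ 20–60. The
asymptotic p instead tracks the permutation **mid-p** (half weight on
ties); the tests check Monte-Carlo agreement with exact enumeration at
3 SE and asymptotic-versus-mid-p agreement within 0.02, which is what
actually holds for discrete tables.

Survival uses Kaplan–Meier product-limit estimates and the two-group
log-rank test (lifelines). With no censoring the KM curve equals the
empirical survival function exactly (tested). Zero events make the
log-rank statistic undefined and raise.

## Bisulfite-sequencing PCR

Only the converted top strand is modeled, matching BSP primer design
(cytosine-free forward primer, guanine-free reverse primer). Clones
are assumed pre-aligned and equal-length to the amplicon — Sanger
clone sequencing of a fixed PCR product — so no indel alignment is
attempted. Calls at CpG positions are C → methylated,
T → unmethylated, anything else ambiguous; ambiguous calls drop out of
both numerator and denominator of methylation fractions. Conversion
efficiency is estimated from non-CpG reference cytosines, and clones
below 0.95 are flagged excluded (standard BSP QC). Amplicon location
requires each primer to match the fully-converted reference exactly
once; zero or multiple matches raise, naming the count.

## Synthetic data: what it emulates and what it does not

The generators produce data with the statistical structure the
analysis assumes, plus planted truth:

- **Methylation.** Beta(μκ, (1−μ)κ) noise around a gene baseline
  μ ~ U(0.05, 0.3) (planted-activated genes start at U(0.5, 0.8) so
  they can lose methylation); concentration κ = 50 gives a site SD of
  ≈ 0.05–0.06, typical of array betas. Planted tumor shifts decay from
  the TSS as effect · exp(−offset²/2σ²) with σ = 500 bp, emulating
  CpG-island-centered hypermethylation. Each gene carries 8 promoter
  sites plus 16 flanking sites covering ±3 kb so the same cohort feeds
  the screen and the meta-profile.
- **Expression.** Log-normal with per-gene baseline log2 level
  U(3, 8) and sample SD 0.5 log2 units; planted genes shift by
  ±2 log2 units in tumors.
- **Cell lines.** For planted genes, per-line promoter beta spans
  U(0.1, 0.9) and log2 expression decreases with beta at 4 log2 units
  per unit beta plus noise; unplanted genes have uncoupled beta and
  expression.
- **Clinical cohort.** 44 patients, half in a latent low-expression
  group; tumor expression separates latent groups by 2 log2 units.
  Covariates are drawn with odds ratios against the latent group
  chosen to mimic a cohort where advanced T stage (OR 12), clinical
  stage (OR 9) and smoking (OR 4.5) associate with low expression
  while sex does not; survival is exponential (control median 60
  months) with hazard ratio 3 for the latent-low group under
  independent uniform censoring on 12–84 months.
- **Bisulfite clones.** Bernoulli per-CpG methylation, conversion of
  unmethylated Cs at rate 0.99, substitution errors at 10⁻³. The
  default 10 clones reflect typical BSP clone counts.

Defaults (200 genes, 10 + 10 planted, 50 vs 50 samples, Δβ = 0.3,
log2FC = 2) are the conditions at which recovery properties are
stated; they keep the full pipeline under ~3 s and the complete test
suite under half a minute on one CPU. What passing tests on these
cohorts does **not** show: robustness to tumor purity and cell-type
composition (betas are not mixtures), probe cross-reactivity, batch
effects, correlated neighboring CpGs beyond the shared gene baseline,
multi-TSS transcript structure, or count-based expression noise
(expression is log-normal, not negative binomial). Real-data use
should treat the thresholds as starting points, not calibrated
values.

Every generator is a pure function of its configuration; sub-streams
are spawned deterministically from the seed, so any stage can be
regenerated independently and bit-identically.

## Numerical and design choices

- Mann–Whitney p-values come from the exact method where sample sizes
  permit (scipy's default policy), otherwise the tie-corrected normal
  approximation; the fully-tied case is short-circuited to p = 1.
- BH q-values are computed by statsmodels and are cross-checked
  against a literal step-up enumeration in the tests.
- Ranking and dichotomization tie-breaks are deterministic and
  documented (lexicographic gene id; ties to low).
- The pipeline validates configuration before running any stage and
  fails before touching outputs if a selected stage's inputs are
  missing; a partially failed run still writes a manifest naming the
  stages that completed.

## Known limitations

- Single-TSS gene models only; transcript-level promoters are out of
  scope.
- The screen tests each gene marginally; no spatial smoothing across
  neighboring sites or genes.
- The location (4×2) association is standard chi-square only; exact
  r×c tests are not implemented.
- BSP analysis has no indel handling and models no strand-specific
  artifacts.
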