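# Methods

This note documents the statistical models, the defaults and why they are
set where they are, what the synthetic cohorts do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Catalog

The pathway catalog is a TSV of gene symbols with one or more of six
functional categories (GTPase, GEF, GAP, GDI, kinase effector, non-kinase
element), coding length (bp), GC fraction, and — for GEFs/GAPs — a GTPase
substrate (RHOA, RAC1, CDC42, or UNKNOWN). Multi-domain proteins carry
several categories (e.g. a DH-domain exchange factor that also contains a
GAP domain); the census counts such a gene once per category, so the
per-category sum exceeds the unique total by the number of extra
memberships. Substrate annotations are only permitted on GEF/GAP entries;
substrate tallies report percentages over the full tallied list by default
(configurable to substrate-annotated members only), and UNKNOWN never
enters a numerator.

## Mutation-burden enrichment

Hypermutated samples are removed before any burden statistic: a sample is
flagged when its total mutation count exceeds 4.5× the cohort mean, with
the mean computed once over all samples (non-iterative, so the threshold
does not drift as samples are removed). Gene load counts protein-altering
records only (missense + truncating + other; synonymous excluded, since the
enrichment question concerns protein-altering burden and downstream
selection analysis treats synonymous mutations as neutral background —
configurable). Prevalence is the fraction of retained samples with ≥ 1
counted mutation in the gene.

The null is resampled: pathway genes are binned into deciles of log₁₀
coding length (bin edges computed on the pathway list; outer edges open),
and each of the 1,000 background lists reproduces the pathway's per-bin
counts exactly, drawn without replacement within a list and independently
across lists, from a background pool that excludes pathway genes. A list's
statistic is its total load (or pooled carrier prevalence). The observed
statistic is referred to the Poisson upper tail `P(X ≥ obs)` at
λ = mean per-list statistic; prevalence is first scaled to expected carrier
counts (fraction × n). The background ensemble's Z-score is reported as
effect size alongside p. The combination of an ensemble Z-score with a
Poisson tail is deliberate: the Z-score describes where the observation
falls in the resampled distribution, while the Poisson tail supplies a
calibrated p-value for a count statistic whose null mean is estimated by
the ensemble. A Shapiro–Wilk statistic on the background distribution is
reported as a diagnostic but never gates the test. BH is the FDR method
throughout the package, with cohort-level significance at FDR < 0.05.

## Selection and hotspot post-classification

dN/dS q-values and mutation-cluster tables are consumed from external
tools, not recomputed. Classification uses strict thresholds mirroring the
tier definitions: significant positive selection at `qglobal < 0.01`, then
`qmis`/`qtrunc < 0.01` decide missense-selected, truncation-selected, or
both. A gene significant globally but in neither sub-statistic is surfaced
with a warning and classed `none` (the case does not arise in practice).
Hotspot summaries report, per gene and cohort, the fraction of each
mutation class falling inside cluster positions (flag at strictly > 30 %)
and the fraction of cohort samples carrying an in-cluster mutation (flag at
strictly > 3 %). Prevalence is per-cohort by default with a pooled option,
since the pooled-versus-per-cohort convention is not fixed by the tier
definition.

## Expression pipeline

Order is fixed: AAIC → lowest-quartile filter → within-lane GC
normalization → between-lane full-quantile normalization → NB differential
expression. The run manifest records per-stage in/out counts and the run is
bit-reproducible.

- **AAIC**: per-sample score = mean Pearson correlation of log₂(count + 1)
  against all other samples; samples below 0.6 are removed in a single
  pass. Mean (not minimum) pairwise correlation is used; an undefined
  correlation (constant sample) counts as 0, which removes such samples.
- **Lowest-quartile filter**: genes with mean count strictly below the
  25th percentile (linear interpolation) of gene means are dropped.
- **Within-lane GC**: per sample, a lowess fit (frac 0.5, 2 robustness
  iterations) of log₂(count + 1) on GC fraction is subtracted and the mean
  log level restored, then values re-exponentiated and clipped at 0. Tied
  GC values receive the mean fitted value of their tie group so the result
  is exactly equivariant to gene order. The contract on simulated data with
  a planted GC trend is a post-normalization |Spearman| < 0.1 per sample.
- **Between-lane**: full-quantile normalization; every sample's sorted
  values become the per-rank mean of the sorted input columns, rank order
  is preserved, and tied values receive the mean of the quantile values
  their tie group spans. With ties the sorted multisets of different
  samples can differ by that averaging; the identity is exact on tie-free
  data.

### NB differential expression

The test is authored here rather than delegated: per gene, group means
m₁ (tumor) and m₀ (normal) give `log2fc = log₂((m₁+0.5)/(m₀+0.5))` (0.5
pseudo-count for stability near zero; groups with all-zero counts are
flagged). Dispersion α (variance μ + αμ²) is estimated per gene by
method-of-moments `(s² − m)/m²` pooled across groups with df weights,
clipped at 0, and shrunk with weight 0.5 toward a trend `α(μ) = a + b/μ`
fitted by non-negative least squares — the standard mean–dispersion
shrinkage compromise at cohort-scale replication. The Wald statistic
divides log2fc by its delta-method standard error from the NB variance of
each group mean, and is referred to a Student-t distribution with
n₁ + n₂ − 2 degrees of freedom rather than a normal: with ~20 samples per
group the plug-in variance makes a normal reference anticonservative, and
the t reference restores type-I calibration (verified against a binomial
CI in the suite). Calls use |log₂FC| > 1 and BH FDR < 0.01. Swapping the
group labels negates every log2fc exactly, and FDR is monotone in p.

### DE-count enrichment, pan-cancer classing, substrate tallies

The number of DE pathway genes is compared with DE counts in length-matched
resampled lists (same machinery as the mutation null; Poisson upper tail at
the background mean). Pan-cancer classing per gene over the cohorts where
it was tested: breadth = (n_up + n_down)/n_tested; tiers at strictly > 50 %
and > 25 %; class `pan_up`/`pan_down` when one direction dominates and
breadth > 25 %, `mixed` on a direction tie or when both directions occur
below the breadth bar, `restricted` for narrow single-direction
deregulation, `none` with no DE cohort. Single-direction genes at or below
the 25 % breadth bar are classed `restricted` regardless of the absolute
cohort count — the class separates broad from narrow deregulation, and
breadth is the operative notion once cohort panels vary in size.

## Copy-number integration

Thresholded calls map directly: −2 deep deletion, −1 shallow deletion, 0
diploid, +1 shallow amplification, +2 deep amplification. Deep and shallow
alterations are analyzed separately, and prevalence (> 10 % bar, strict) is
computed per alteration class, matching the separate deep/shallow analyses;
a pooled option exists. The SCN-vs-diploid contrast reuses the NB engine
with groups = altered-at-depth vs diploid tumor samples; groups below 2
samples are flagged not-testable rather than erroring. The tumor-vs-normal
axis of the concordance call restricts tumors to samples diploid for the
gene under test, so the two contrasts are not confounded by the alteration
itself. Concordance: `reinforcing_up` (amplification, both contrasts
significant and positive), `reinforcing_down` (deletion, both negative),
`opposing` (both significant, discordant signs), else `inert`.

Driver co-occurrence binarizes calls at one depth and direction and applies
the one-sided (enrichment) Fisher exact test per pathway-gene × driver
pair, BH-adjusted within cohort and depth, linked at adjusted p < 0.05. The
one-sided alternative is the deliberate default — the scientific question
is co-occurrence, not any association — with the two-sided test available.
Degenerate margins (a gene altered in no or all samples) yield p = 1 with a
flag. The driver list is an input file, not a bundled database, to avoid
external-version dependence.

## Co-expression and GSEA

Spearman correlations use average ranks for ties; p-values come from the
t approximation, or from exact enumeration of all rank permutations for
n ≤ 9 samples. Significance is BH FDR < 0.05 within cohort (the threshold
is a package decision — the source analyses encode p graphically without
fixing a cutoff — and is configurable). Cross-cohort summaries report the
percentage of tested cohorts significant (strict > 50 % / > 25 % tiers) and
the dominant sign among significant cohorts, `mixed` on ties.

Pre-ranked GSEA uses the weighted Kolmogorov–Smirnov running sum with
weight exponent 1 (hit increments ∝ |score|, miss increments uniform); the
ES is the extremum of the running sum, evaluated at the positions where
extrema can occur. The null is gene-label permutation: `n_perm` random
placements of a same-size set (default 10,000), NES = ES divided by the
mean |ES*| of same-sign permutations, and
p = (1 + #{|ES*| ≥ |ES|, same sign}) / (1 + #same-sign). FDR is BH on the
permutation p-values rather than the NES-histogram construction — simpler
and calibrated. Sets are intersected with the ranked universe; sets larger
than 800 or smaller than 5 after intersection are dropped. ES is invariant
to positive rescaling of scores (exactly order-invariant at weight 0), and
a fixed seed makes the permutation p bit-reproducible. Top processes are
ranked by median NES across cohorts, ties broken by set name for
determinism.

## Dependency screens

A line counts as dependent when its score is strictly below −0.5;
pan-essential requires strictly more than 10 % of lines dependent. Lineage
vulnerability compares each lineage (minimum 3 lines; smaller lineages
skipped with a warning) with all remaining lines: Welch's unequal-variance
test supplies p (the robust default; Student's pooled-variance test is
available by configuration), BH FDR runs over all gene × lineage tests, and
the flag requires |median_in − median_out| > 0.5 with FDR < 0.01. Direction
is reported separately (`sensitizing` for negative differences — knockout
depletes the lineage — `protective` for positive), since knockouts can
either reduce or increase proliferation. Adding a constant to all scores
leaves median differences and flags unchanged, and results do not depend on
column or lineage ordering.

## Synthetic cohorts

The generators produce every input the pipeline reads, with each planted
effect recorded in a ground-truth sidecar (gene, effect type, magnitude) so
recovery tests never re-derive truth from data. Defaults are set to
TCGA/DepMap-like desk-scale conditions:

- **Mutations**: per gene and sample, Poisson counts at rate × length
  (default 10⁻⁶ per bp per sample ≈ 1 mutation/Mb); hypermutators (2 % of
  samples) multiply the rate by 20; catalog genes optionally carry a burden
  enrichment factor; variant classes are categorical (25 % synonymous,
  55 % missense, 12 % truncating, 8 % other) with uniform protein
  positions. Hypermutation is a rate multiplication, not a separate
  process — sufficient to exercise the 4.5× filter.
- **Expression**: NB counts (variance μ + αμ², α = 0.1) around log-normal
  baseline means (median ~100); tumor means multiplied by 2^planted-log2fc;
  each sample's log mean tilts linearly in centered GC by a per-sample lane
  factor, so within-lane normalization has a real signal to remove.
- **Copy number**: calls drawn per gene × tumor sample from a categorical
  over {−2…+2} (80 % diploid by default); altered cells re-draw counts from
  the stored generating mean times 2^(dosage × call), dosage default 1
  log₂/copy; planted driver genes are deep-amplified with odds multiplied
  by a configured odds ratio when the paired pathway gene is amplified.
- **Dependency**: Normal(0, σ = 0.2) scores; pan-essential genes shifted by
  −1 everywhere; lineage-specific genes shifted by the configured amount
  (default −1) in one lineage; 220 lines split evenly over 11 lineages.

Not emulated: mutational signatures and trinucleotide context,
linked-segment CNV geometry, isoform structure, batch effects beyond the
GC/lane trend, and single-cell structure. Passing recovery tests therefore
demonstrates correctness of the statistics under the stated generative
models, not robustness to every artifact of real cohorts.

## Problem sizes and verification

The suite verifies each statistic against an independent oracle: set-union
counting for the census, naive per-record tallies for load/prevalence and
hotspot fractions, direct Poisson tail sums, brute-force hypergeometric
tails for Fisher (agreement to 10⁻¹²), exhaustive permutation enumeration
for small-n Spearman and for GSEA (all 15,504 placements of a 5-gene set in
a 20-gene ranking), an exhaustive rule-grid for pan-cancer and concordance
classing, and parameter recovery plus type-I calibration on simulations.
Calibration and power of the mutation enrichment test are checked with a
120-gene catalog, 2,000 background genes, 200-sample cohorts, 100-list
ensembles, and 200/100 replicates; DE recovery with 20 vs 20 samples,
dispersion 0.1, 50 replicates; dependency nulls with 100 replicate 66-line
matrices. These sizes keep the full suite and the acceptance script in the
tens of seconds while leaving the binomial confidence bands tight enough to
detect miscalibration.

## Known limitations

- The NB test's t reference is a small-sample calibration device, not an
  exact likelihood-based test; at very low counts (means ≪ 10) its
  calibration degrades.
- The lowess GC fit assumes a smooth trend; pathological GC distributions
  with large tie groups reduce it to a coarser step fit.
- The Poisson tail treats the background mean as known; the ensemble's
  Monte-Carlo error in λ is ignored (negligible at ≥ 100 lists).
- The pipeline's co-expression and GSEA stage operates per cohort; the
  cross-cohort summary assumes cohorts are independent.
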