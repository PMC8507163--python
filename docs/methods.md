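# Methods

This note documents the statistical model, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Pipeline and preprocessing

Stages run in a fixed order: filter → quantile normalize → log2 →
weights → per-contrast enrichment → cross-disease comparison → target
mapping. One seed governs every stochastic stage, and the run manifest
records the effective parameters and input digests.

Filtering drops miRNA rows that are all zero, contain a missing value,
or have zero variance, then drops any sample still carrying missing
values (each rule separately switchable, because conventions differ on
whether zero-variance screening applies to rows, samples, or both).
Quantile normalization uses the rank-mean reference — the across-sample
mean of the within-sample order statistics — and resolves ties within a
sample by averaging the reference values across the tied ranks (the
convention of limma's `normalizeQuantiles`; dialects differ, so it is
stated here and asserted by an idempotence test). The log2 transform
applies a pseudocount of 1.0 by default, safe for zero-containing
synthetic inputs; 0 is allowed by flag since all-zero rows are filtered
first.

## miRNA-pathway weights

W_ij = 1 − p_ij, where p_ij is the hypergeometric upper-tail
probability of the observed target/gene-set overlap. Two code paths
exist: an exact integer-arithmetic tail sum (`math.comb`, default for
any scalar call — correct to full float precision) and the vectorized
`scipy.stats.hypergeom.sf` survival function used when building the
full weight matrix. Tests pin both against exhaustive subset
enumeration for genomes up to 12 genes.

The genome size *m* defaults to the union of all pathway genes and all
target genes, since no fixed universe is implied by the inputs; it can
be overridden. Pathway miRNA-set membership uses the weakest defensible
rule — at least one shared target gene (`min_overlap=1`) — with an
optional additional `p_ij ≤ p_max` filter. W is used as-is in the
ranking score (no cap or transform). p_ij values are weights, not
hypothesis tests, and receive no multiple-testing correction.

## Differential scores and ranking

The default per-miRNA differential score is the signal-to-noise ratio
(μ_case − μ_control)/(σ_case + σ_control) on log2 data, with each
group's sample standard deviation (ddof = 1) floored at 0.2·|μ| of that
group; identical constant groups score exactly 0. Welch's t is
available as an alternative. The floor makes the statistic
scale-stable, but note that on log2 intensities around 6–8 it
dominates the denominator, so scores are effectively scaled mean
differences.

Ranking is per-pathway by default (`(1 + W_ij)·DE_i`, the score the
weight matrix exists for); a single global list using each miRNA's
maximum weight is available (`ranking="global"`). Ties are broken by
lexicographic miRNA id, making every ordering reproducible.

An optional differentially-expressed-miRNA gate (BH-adjusted Welch FDR)
defaults to the vacuous threshold 1.0, i.e. all miRNAs enter the
ranking — matching the convention of admitting every miRNA with
FDR < 1.

## Running-sum enrichment and significance

The running sum uses the weighted KS form with exponent p = 1 by
default (exposed as `--weight-exp`; p = 0 gives the classic unweighted
statistic whose profile provably returns to zero). ES is the signed
maximum deviation; on |deviation| ties the earliest rank wins, enforced
with a 1e-12 tolerance so floating-point dust cannot flip a peak or an
ES sign. Core (leading-edge) miRNAs are the members at or before the
peak for ES ≥ 0, at or after it for ES < 0 — the standard leading-edge
rule, adopted because the literal "members where the running sum is
negative" reading is not interpretable for positive-ES pathways.
Derived statistics: `mir_pct` (fraction of the list before/after the
peak), `tag_pct` (fraction of members in the core) and
`signal = tag_pct · (1 − mir_pct) · N/(N − N_H)`.

Significance uses phenotype-label permutation: each of `n_perm`
permutations recomputes DE, miRScores and the per-pathway ranking.
NES = ES / mean(|same-sign null ES|); nominal p is the same-sign
exceedance fraction with add-one smoothing; FDR q is the standard
pooled same-sign normalized-null ratio (null NES are each normalized by
their own pathway's same-sign null mean and pooled across pathways).
With fewer than seven samples in a group the test switches, with a
warning, to miRNA-identity permutation over the fixed observed ranking.
Pathway miRNA sets smaller than 3 or larger than 500 members are
skipped, because the running-sum statistic degenerates at the extremes;
both bounds are exposed. Positive NES means up-regulation in the case
group (the group named first in the phenotype labels).

## Cross-disease comparison

Common pathways must be significant (q ≤ 0.25 by default) in both
contrasts, with opposite directions unless disabled. The score-matrix
cell for miRNA *i* and pathway *j* is defined only when the miRNA is a
core member of that pathway in *both* contrasts: it is the mean of the
two per-contrast scores, where a per-contrast score is the miRNA's
miRScore in that pathway's ranked list rescaled by the list's maximum
absolute miRScore (bounding cells to [−1, 1]). That cell quantity is
not uniquely determined by the published tables, so it is isolated in
one place (`core_scores` on each enrichment result) and every
aggregation — nonzero row/column means, core counts, pairwise shared
counts, selections — is tested against the packaged reference grid
independently of the choice. Zeros encode absence; means and counts use
strictly nonzero entries, and a genuine score of exactly zero is nudged
to 1e-12 with a warning so it stays distinguishable.

Pathway selection filters on the first contrast's NES ≤ −2 (the bound
is contrast-A-only because, in the emulated comparison, only that
contrast's NES distribution motivated a threshold while the other's was
confined to a narrow band), then ranks by |nonzero column mean| and
core count, keeping the top 3. miRNA selection keeps rows nonzero in
every selected pathway, ranked by nonzero row mean, top 5. All
tie-breaks are by identifier.

One known discrepancy in the packaged reference grid: the ERBB column
prints a mean consistent with dividing by 11, but the column has 10
nonzero entries. The implementation always divides by the nonzero
count; the ERBB printed mean is therefore not asserted anywhere.
Similarly, where a figure caption and the grid disagree on the lung
cancer pathway's core count (10 vs 11), the grid's nonzero count (11)
is used.

## Synthetic data: what it emulates, and what it does not

The generator draws a gene universe (default 20 000 genes, the human
protein-coding scale), pathway gene sets (default 40, sizes 30–120),
per-miRNA target sets (10–60 targets), and two two-group raw-intensity
expression matrices shaped like the emulated studies: contrast A with
1308 miRNAs over 19 vs 8 samples, contrast B with 1145 miRNAs over
20 vs 20. Baseline log2 expression is Normal(6, noise_sd); raw values
are 2^x so the preprocessing chain is exercised on the path real data
takes.

Planted structure is at the target level: each planted pathway gets
driver miRNAs (default 6) with a majority (default 75%) of their
targets inside its gene set, which makes their weights and membership
high by construction; drivers then receive a ±effect_size log2 shift
(default 2.0) in the case group of the stated contrast. The default
planting is balanced — three pathways down in A and up in B (the
cross-condition signature of interest) and three the opposite way —
because real two-group contrasts carry regulation in both directions,
and a strictly one-directional plant makes quantile normalization
shift every unperturbed miRNA coherently the other way.

Deliberate idealizations, and hence limits on what passing tests show
about real data:

- **Disjoint pathway gene sets.** Real collections overlap heavily;
  disjointness (together with drawing drivers' off-pathway targets
  outside all gene sets) keeps the planted truth attributable to
  exactly one pathway, which is what a recovery test needs. Pipeline
  behaviour on overlapping pathways (correlated enrichment across
  related sets) is not probed.
- **Independent miRNAs and samples.** No miRNA co-expression, no
  paired-sample correlation, no batch or probe effects.
- **Quantile-normalization coupling.** Even at the default scale, a
  strong asymmetric plant leaves a small coherent shift in non-driver
  differential scores after normalization (the raw-scale up- and
  down-shifts 2^±3 do not cancel). In the balanced 20 vs 20 contrast
  this inflates opposite-direction false positives relative to the
  19 vs 8 contrast; the calibration and recovery checks therefore run
  on the 19 vs 8 design, and conclusions about the 20 vs 20 design's
  false-positive rate under strong signal should not be drawn from
  them.
- **Pooled-FDR granularity.** The GSEA-style pooled FDR is known to be
  distorted when a large fraction of a small collection is truly
  enriched; the default of 40 pathways with 6 planted (15%) keeps the
  distortion modest. Much smaller collections shift null pathways'
  q-values downward mechanically.

## Problem sizes used by the checks

The packaged reference-grid checks are exact arithmetic on a 20 × 7
grid and run in milliseconds. The combinatorial oracles cover every
genome up to m = 12 (hypergeometric tail, ~3200 cases) and every member
placement for ranked lists up to length 10 (~2000 cases). Null
calibration uses a no-effect study with 200 miRNAs and 20 pathways at
200 permutations; planted-signal recovery uses the full default study
shape (1308 miRNAs, 40 pathways, 19 vs 8) at 200 permutations. These
sizes keep the whole suite under a minute on one CPU while leaving each
check statistically meaningful.
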