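# Methods

This note documents the models, parameter choices, and numerical
decisions behind `cghcnv`, and what the synthetic-data experiments do and
do not demonstrate about real arrays.

## Signal model of the simulator

A spot measuring a probe with planted copy state *c* ∈ {1, 2, 3} in
sample *s* yields, on the log2 scale,

    M_raw = d · (log2(c/2) + ε) + b + g(row, col)

with *d* = +1 on forward and −1 on reverse chips, ε ~ N(0, σ²) the
measurement noise attached to the biological ratio, *b* the spot-specific
dye bias (a fixed property of the spot, identical on every chip), and
*g* a smooth low-order polynomial over normalized grid coordinates
(an individual chip's spatial artifact).  After orientation adjustment
(reverse M negated) the bias enters as +b on forward and −b on reverse
chips — exactly the ±Dye coding of the correction model, so the simulator
and the corrector agree by construction and the correctness of the
*estimate* is what the tests exercise.

Raw intensities are reconstructed as `net = 2**(A ± M_raw/2)` with
A ~ N(10, 1), plus a lognormal additive background recorded in the
background channels, so foreground-minus-background subtraction recovers
M exactly in the noise-free limit.  A configurable fraction of dead spots
(foreground below background) and one rectangular high-variance block
(default SD 1.0, emulating a damaged chip region) exercise the QC path.

Copy state 0 is deliberately absent: the analysis this package
re-implements observed no homozygous deletions, and the calling threshold
logic (below) does not depend on it.

The pooled reference is treated as noise-free apart from measurement
noise: pooling many reference individuals averages away their individual
variation, and no published estimate of the residual pool variance was
available to calibrate against; any residual pool heterogeneity would act
as extra per-probe noise shared across arrays.

### Default study conditions

All defaults were fixed once, before any acceptance measurement, to
mirror the study design the pipeline addresses, scaled to desk size:

| parameter | default | rationale |
|---|---|---|
| genome | 16 chromosomes × 6.25 Mb = 100 Mb | scale model (~1/28 of a 2.83 Gb genome) keeping per-chromosome probe counts near 800 |
| probe spacing | 7.9 Kb median, ±10% jitter, 60-mers | the tiling platform's published median spacing |
| replicate spots | 1% of loci duplicated | exercises replicate averaging |
| samples | 3, each forward + reverse (6 arrays) | the dye-swap design |
| planted CNVs | 40/sample, 50–500 Kb, 70% shared across samples | per-sample CNV burden ~11% of the scale genome; sharing mirrors the >70% cross-individual consistency of real CNVs |
| noise σ | 0.15 log2 units | typical per-spot ratio noise for tiling aCGH |
| dye bias | N(0, 0.05) everywhere + ±0.4 offsets on 25% of spots | reproduces the regime where roughly a quarter of spots carry detectable bias |
| gradient amplitude | 0.05 log2 units | visible but small spatial trend |
| gene fraction | 21% of the genome, lognormal gene lengths (median ~16 Kb) | the whole-genome gene fraction the coverage table compares against |

## Preprocessing decisions

- **Background correction** is plain foreground − background; spots with
  a non-positive result in either channel are flagged, not offset.
- **Weighted loess**: binary weights — 1 when −1 ≤ M ≤ 1, else 0 — with
  span 0.3, degree 1 (local linear), 3 robustness iterations
  (statsmodels `lowess`); the fitted value is subtracted from *all*
  spots.  Binary weighting is the literal reading of "coefficients
  calculated from the M values between −1 and 1" and guarantees the fit
  equals one computed with the excluded spots removed.  The curve is
  evaluated by `xvals`, with constant extrapolation beyond the weighted
  A range.
- **Region QC**: the chip grid is tiled into 10×10 windows; a spot is an
  outlier when |M − window median| exceeds 3 normal-consistent *global*
  MADs, and a window with >40% outliers is flagged wholesale.  The global
  (not window-local) MAD matters: a uniformly noisy window is not
  outlier-rich relative to its own spread.  Because consecutive probes
  map to consecutive grid columns, a real CNV contributes at most one
  row's worth of spots to any window and cannot trigger the rule.
- Missing-M spots are dropped, never imputed.

## Dye-bias model

Per spot, OLS on M_i = α + β·Dye_i + e_i over the six oriented values;
with the balanced 3+3 design α is the grand mean and β half the
forward−reverse difference.  β's significance uses an ordinary t with
n−2 = 4 df — not an empirical-Bayes moderated statistic; moderation is an
implementation detail of a particular toolchain, and the plain test's
type-I error is verified at the nominal 5% on 10,000 null spots.  Spots
missing on some arrays are fitted on the remainder when both dye levels
survive and n ≥ 3; otherwise skipped and passed through uncorrected.
Dendrograms (Ward, Euclidean, complete-case probes) are exported as
Newick text so the diagnostic is assertable, not just plottable.

## Segmentation

Circular binary segmentation with the pooled-SD two-sample t statistic
over all non-wrapping arcs (a wrapping arc is a complement with the same
|T|), ties broken lexicographically.  Perfect separations (zero pooled
SD with distinct means) score +∞, with a cancellation guard of
1e-9·(max|x|+1) so constant stretches score 0.  Significance is a
within-stretch permutation test; splits recurse; adjacent segments whose
means differ by < `merge_tol` = 0.05 log2 units are re-merged afterwards
(the "undo splits" safeguard against over-segmentation — well below the
0.5 calling threshold, so it cannot erase a real CNV edge).

Defaults α = 0.01, nperm = 10,000 (the conventional CBS settings).  The
pipeline's default configuration uses nperm = 2000 with a sequential
permutation loop: blocks of 64 permutations stop as soon as significance
is impossible (exceedances > α·(nperm+1) − 1; this decision is exact) or
after ≥200 exceedance-free permutations (reported p = 1/(m+1) ≤ 0.005,
decisive at any α ≥ 0.01 in use).  The early-success stop is the one
approximation: it reports a conservative p upper bound rather than the
full-nperm estimate.  All draws flow from per-chromosome sub-seeds, so
results are bit-reproducible.

## CNVR calling

Cores are maximal runs of ≥3 consecutive probes with smoothed M beyond
±0.5 — just under log2(3/2) ≈ 0.585, the expected ratio of a single
duplicated allele, so a true one-copy gain clears the threshold while
normalization wobble does not.  "Consecutive" imposes no maximum genomic
gap by default (a `max_gap` knob exists for sensitivity analysis).  The
5 Kb flank approximates one probe's single-sided coverage (half the
median spacing).  Same-status regions of one sample that touch after
extension are merged, to avoid double-counting coverage.  Cross-sample
merging is a status-stratified union treating book-ended regions as
overlapping; support is the union of contributing samples.  Coordinates
are 0-based half-open (BED) everywhere.

## Interval analysis

Merged interval sets are sorted disjoint arrays; overlap queries use
prefix-sum coverage (O(log n) per query), cross-checked in the tests
against a per-bp boolean-mask oracle.  The permutation null redraws the
query's exact interval lengths uniformly over the genome — chromosome
chosen ∝ (length − interval + 1) valid start positions — and sums
per-interval feature overlap without re-merging the placed intervals.
The p-value is the tail-directed (k+1)/(n+1) estimator (never exactly 0),
and a z-score (observed − null mean)/null SD is reported alongside for
the normal-approximation reading.

## Enrichment and expression

Hypergeometric over-representation is upper-tail P(X ≥ k) via the exact
survival function; BH step-up adjusts across sets.  Target sets of
multiple mature forms of one miRNA are unioned before testing.  Gene ids
are opaque strings — orthology mapping between id spaces is a
preprocessing concern outside this package.

Probeset collapsing keeps, per gene, the probeset most often attaining
the gene's per-sample maximum (ties in a sample credit all attaining
probesets; ties in the count are averaged sample-wise).  Differential
expression is a Welch t-test on log2 intensities (pooled-variance
variant behind `equal_var=True`); the test scale is log2 for variance
stabilization, matching the log2 fold changes reported.  FDR 0.2 is the
calling threshold, so >80% of called genes are expected truly
differential.  Consistency labels: gain∧up or loss∧down → consistent,
opposite → inconsistent, not significant → untested; genes hit by both a
gain and a loss region are excluded as directionally ambiguous.

## What the synthetic experiments show — and what they cannot

Passing tests demonstrate that each stage recovers what the generator
planted under the stated noise model: ≥90% of planted CNVs are recalled
with matching status, boundaries land within one probe spacing + 5 Kb
(95th percentile; the median is within the 5 Kb flank itself), null
calibrations of the dye-bias test, the CBS split test, and the interval
permutation test sit at their nominal levels, and the clustering
diagnostic reproduces the dye-separation/pair-rejoining pattern.  A
boundary-error criterion is asserted at the 95th percentile rather than
the per-boundary maximum: across ~480 stochastic boundaries, occasional
≥2-probe misplacements are expected behavior of any change-point
estimator at a 3.9σ jump, and a maximum over hundreds of draws is not a
stable statistic.

The generator does not model probe sequence effects, GC- or
gap-structured genomes, cross-hybridization, correlated (wave) noise, or
reference-pool heterogeneity; real-array performance therefore cannot be
inferred from these numbers, only the correctness of the estimators
under their assumed model.  Headline figures from real arrays (counts of
CNVRs, the 23.7% dye-bias fraction, specific depletion p-values) depend
on the deposited hybridizations and contemporaneous annotation databases
and are not reproduced here; the acceptance script instead recomputes
the arithmetic identities those tables imply and the synthetic-study
analogues of each quantity.

## Problem sizes

The default synthetic study (16 × 6.25 Mb, ~12,700 probes, 6 arrays,
nperm = 2000) runs end to end in a few minutes on one CPU; unit tests
use 2–4 chromosome genomes and correspondingly smaller nperm.  These
sizes are the package's chosen study conditions, fixed alongside the
other defaults above.
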