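# Methods

This note documents the models, conventions and numerical choices behind
`cdktrace`, and what the synthetic-data tests do and do not demonstrate.

## The readout and its conventions

The CDK sensor's cytoplasmic:nuclear intensity ratio (C:N, dimensionless)
rises with CDK activity.  All trace times are minutes relative to the
anaphase of the mother cell (anaphase = 0; mother samples are negative).
Conventions implemented:

* **G1 snapshot** — the ratio at the sample nearest 25 min post-anaphase,
  nearest-neighbor with no interpolation, tolerance one sampling interval
  (traces are sampled every 5 min; reading a single frame is what one
  does with a movie).
* **CDK^low fixed-threshold call** — a cell is quiescent-by-threshold
  when some run of ≥ 3 *consecutive* post-anaphase frames lies strictly
  below 0.19.  "Below" is strict; a ratio exactly at 0.19 never counts.
  The anaphase-aligned t = 0 frame counts as the first post-anaphase
  frame.
* **Trace QC** — a usable trace has a t = 0 sample (an observed
  anaphase), spans ≥ 20 min after anaphase, and has no sampling gap
  larger than twice the nominal interval.  QC returns machine-readable
  reasons and never raises.

## Ratio quantification

Images are background-subtracted before measurement.  The background is
estimated by grayscale morphological opening with a flat disk footprint
(default radius 50 px, applied as a decomposed footprint sequence for
speed) of a 3×3-mean presmoothed copy of the image, then subtracted from
the original and clipped at zero.  Properties of this estimator: a flat
image maps exactly to zeros; adding a constant offset (camera baseline)
leaves the output unchanged; any bright structure narrower than the disk
keeps its full contrast.  The presmoothing keeps the minimum filter off
the noise floor of EM-CCD-like amplifier noise; without it the background
is underestimated by roughly 3 noise SDs, which biases ratios toward 1.
The classical ball-shaped (non-flat) kernel was deliberately not used: it
creeps upward under wide bright objects by the chord sagitta, so even a
noiseless image would not recover its true ratio exactly.

`measure_cell` then takes the mean gray value over a nuclear toroid mask
(annulus excluding the nucleolus) and over a perinuclear cytoplasmic
patch mask; the ratio is cyto/nuc.  Masks are binary (nonzero =
included), must be disjoint and nonempty, and a zero nuclear mean is an
error rather than an infinite ratio.  Pixel coordinates are 0-based
row-major; intensities are arbitrary units — only ratios are interpreted.

## Permutation statistics

Two statistics:

* single timepoint: `|mean(group1) − mean(group2)|`;
* time course: per-timepoint mean trend lines on the shared grid, then
  the L1 distance `Σ_t |x̄₁(t) − x̄₂(t)|` (the area between the trend
  lines at discrete timepoints).  Timepoints observed in only one group
  are dropped from the sum and logged.  No smoothing or interpolation.

The null distribution re-partitions the pooled data at random, without
replacement, into two groups of the original sizes.  For time courses the
unit of permutation is the whole trace — timepoints of one cell are never
split across groups.  The p-value is the fraction of replicates whose
statistic strictly exceeds the observed one; when none exceeds it the
result is reported as a floor, p < 1/n_reps, since the true value is
below what the replicate count resolves.  Strict exceedance is
anti-conservative as p → 0, which the floor convention absorbs.  Two
numerical details:

* replicate statistics that are mathematically tied with the observed one
  can land an ulp above it along the vectorized path, so the cutoff for
  "strictly greater" is `observed × (1 + 1e-9)`;
* the default replicate count is 10⁵ (configurable upward; the floor
  rescales accordingly).  Batches of 2000 replicates are vectorized as
  matrix products against a traces × timepoints value/indicator pair.

`exhaustive_permutation_oracle` enumerates all C(n, n₁) partitions for
inputs of ≤ 12 observations (or traces) and returns the exact exceedance
proportion.  It is both a user-facing exact test for tiny groups and the
independent check of the sampled test.

The procedure is sometimes described as "bootstrapping" in this field
even though sampling is without replacement into fixed-size groups — a
permutation test; this package uses the permutation naming throughout.

The design is unpaired, with no multiple-testing correction (p-values are
reported per comparison).  Test calibration: under a simulated null
(both groups N(0.5, 0.1²), n = 15/15, 1000 trials, 2000 replicates) the
rejection rate at α = 0.05 must lie in [0.03, 0.07].

## Fate classifier

Training builds, at every post-anaphase grid timepoint with both fates
present, an ROC curve over all distinct observed ratios as candidate
thresholds (plus a −∞ endpoint).  Higher ratio scores proliferative; a
sample votes proliferative iff its ratio is *strictly* above the
threshold, so boundary equality votes quiescent.  AUC is the trapezoidal
integral of the (FPR, TPR) path traversed by descending threshold, which
equals the pair-counting (Mann–Whitney) definition with ties counted ½.
The operating threshold maximizes the geometric mean
√(sensitivity × specificity); among exact ties the largest cutoff is
chosen (most conservative toward quiescence).  Single-class timepoints
are omitted and logged.  Fitting is deterministic.

Trace-level prediction votes over *relevant* timepoints:

* traces extending beyond 60 min post-anaphase use all samples with
  t > 60 (strictly) — these timepoints allow near-perfect prediction
  (AUC > 0.9);
* traces of 20–60 min use their last three recorded samples (AUC > 0.8,
  increasing with time);
* traces shorter than 20 min post-anaphase are not classifiable
  (coverage error; `evaluate` reports them as skipped, outside the
  accuracy denominator).

Majority wins; even splits are broken by the latest relevant timepoint's
vote, because prediction power increases with time after anaphase.  Votes
use the nearest trained timepoint within one sampling interval, else a
coverage error.  The AUC floors (0.9 long / 0.8 short) are stored as
classifier metadata and produce warnings when a voting timepoint falls
below its floor; they do not exclude timepoints — they document expected
reliability rather than act as a filter.

`train_test_split` is stratified by fate at whole-trace granularity
(default 75/25, seeded).  Stratification is a package decision: at desk
scale an unstratified split can produce a single-class training set.

Open edge documented rather than resolved: a 20–60-min trace whose last
three samples reach back before 20 min still uses exactly its last three
samples (the rule is applied verbatim).  Per-timepoint classification
uses the shared 5-min grid.

## Synthetic data

`simulate_traces` emulates anaphase-aligned two-fate recordings:

* 5-min sampling from −20 min (mother G2) to +120 min by default;
* a mother-cell G2 ramp rising to the peak ratio (maximal nuclear
  exclusion, `g2_peak_mean` = 1.0 for the GFP-scale sensor) just before
  anaphase, then a drop at t = 0;
* proliferative daughters born at `g1_birth_mean` = 0.35 plus a per-cell
  offset (SD `inc_birth_sd` = 0.13), rising at `inc_slope` = 0.008/min
  (≈ 1.0 by ~80 min, the S-phase scale);
* quiescent daughters fluctuating around `g0_mean` = 0.13 with
  `noise_sd` = 0.04.

Defaults are the in-vivo scale: G0 ratios of ~0.10–0.14 ± 0.04–0.05
(induced G0, adaxial cells, muscle fibers), G1 birth ratios of
0.35 ± 0.14 (vulval precursors, GFP sensor), G2 peak ≈ 1.0.  The
asymmetric spreads matter: G1 ratios vary far more across cells than G0
ratios, so the per-cell birth offset is applied to the proliferative
branch only.  Because that offset is shared along a trace while the
branch means diverge, fate is partly ambiguous shortly after anaphase and
increasingly predictable later — the structure the classifier's
time-resolved rules exploit.  Frame-to-frame noise is additive Gaussian
and independent per timepoint by default (means ± SD are all the printed
data constrain; an AR(1) hook, `noise_ar1`, is provided since real
within-trace autocorrelation is unknown).  A quarter of traces are
truncated to end between 20 and 60 min so both voting rules are
exercised.  Ratios are clipped at 0.

Not emulated: 3-D stacks, photobleaching, cell movement, lineage trees,
segmentation/tracking errors, and the real distribution of trace lengths.
Passing at these conditions shows the pipeline recovers the structure it
assumes — it does not certify the published accuracy on real recordings,
which can only be recomputed from the deposited ratio tables.

`simulate_cell_image` renders background (constant + slow diagonal
shading) + nucleus disk (nucleolus hole at background level) + cytoplasm
annulus + Gaussian read noise, with conservative toroid/patch masks
(2-px margins) and `true_ratio = cyto_mean / nuc_mean`.  With noise and
shading off, the measured ratio equals the true ratio exactly; at the
default noise (read SD 2, shading amplitude 5 on a 10-unit background)
recovery is within ~2%, against a 5% requirement.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: 200-trace
recordings (100 per fate), 150-trace training sets, 1000-trial null
calibrations at 2000 replicates, 10⁵-replicate permutation runs, and
128×128 synthetic images.  The statistics are identical at larger sizes;
only Monte-Carlo resolution changes (the p-floor rescales as 1/n_reps).

## Known limitations

* The xlsx writer serializes 16 significant digits, so ratios round-trip
  through xlsx to one ulp rather than bit-exactly (CSV/TSV are
  bit-exact).
* The wide-sheet importer is best-effort: deposited spreadsheet layouts
  vary, so it assumes time in the first column and one cell per column.
* The rolling-ball dialect is the flat-disk opening described above, not
  the sliding-paraboloid variant; for backgrounds that are genuinely
  curved on the scale of the footprint the two differ.
* No probabilistic fate outputs, no smoothing, no alternative
  classifiers; only the threshold/majority-vote procedure is provided.
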