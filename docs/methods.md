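# Methods

This note documents the models, defaults, and design decisions behind
`songdev`, and what the synthetic tests do and do not establish.

## Data model

One `OntogenyDataset` holds one bird's records across three phases:
first treatment (`T1_PLUS`), withdrawal (`T1_MINUS`, silent), second
treatment (`T2_PLUS`).  Two day axes are carried throughout:
*experiment day* (days since the first implant) anchors everything;
*phase day* (days since the phase's first detected song) aligns
trajectories across birds, while stabilization durations are reported
relative to the phase's implantation day, matching how treatment-to-
stabilization times are conventionally quoted.  The syllable rate is
derived, never trusted from input: SR = 1000/(d+i) Hz for d, i in ms,
defined only for syllables followed by another within the same bout
(bout-final syllables carry no pause and no rate).  Stored SR columns
that disagree with the derived value by >1% trigger a row-listing
warning.

## Segmentation

Syllables are maximal runs of envelope samples strictly above a
per-recording amplitude threshold (the threshold has no universal
default; it is a required parameter chosen once per bird).  Sounds
separated by ≤100 ms share a bout; only bouts spanning ≥750 ms
(inclusive, "at least") are analyzed.  WAV input is reduced to a
rectified moving-RMS envelope (2 ms window by default).  Note one
consequence of the bout rule: syllables whose within-phrase pauses
exceed 100 ms (rates below ~5–6 Hz at long durations) are split into
separate bouts by a strict reading of the gap rule; the synthetic
generator's slow rate class sits in this regime, so segmentation-level
round trips are checked at the interval level, and rate statistics in
the generator are carried in the feature table rather than re-derived
from envelopes.

## Daily histograms and similarity

Feature values are scaled by a per-feature bin width and rounded to the
nearest integer (halves away from zero, so negative Wiener entropies
bin symmetrically).  Defaults: SR 1 Hz; d, i 1 ms; FM, AM 1 native
unit; BW, MF 50 Hz; E 0.1.  The support (bin range) is fixed per
bird × feature to the globally observed range so every day shares one
bin vector.  The reference pattern averages the *frequencies* (not raw
counts) of the last 7 singing days of a treatment, so productive days
do not dominate, and is renormalized.

The similarity of a day to the reference is the Pearson correlation of
the two bin vectors: +1 is an exact copy of the pattern, −1 its
inverse; the statistic is invariant to positive affine rescaling, so
counts and frequencies give identical trajectories.  Zero-variance
vectors make the CC undefined and the day is reported missing, not 0.

Days that belong to the reference window share their sampling noise
with the averaged reference, which would bias their CC upward — and
therefore bias the deterioration of perfectly stable features above
zero.  Such days are correlated against a leave-one-out reference
(the other six window days) instead; the naive behavior remains
available (`leave_one_out=False`).

## Logistic fit and derived statistics

F(x) = a + b/(1+exp((c−x)/d)) is fitted by multi-start least squares
(starts at a = min CC, b = observed range, c = day of steepest observed
rise, d ∈ {5, 15, 40} days, plus mirrored decreasing starts; bound
d ≥ 0.1).  A trajectory "shows a developmental increase" when b > 0.05
and the logistic cuts the residual sum of squares by ≥20% versus the
best constant model; both thresholds are configurable.  Daily gain is
the integer-day difference F(x+1) − F(x), not the instantaneous
derivative.  The stabilization day is the smallest integer day ≥ c
with daily gain < ε = 0.001; d_max is the maximum daily gain and is
undefined for trajectories without a developmental increase.  Group
statistics over stabilization days are only attempted when at least
three birds have defined values.

On noiseless logistic inputs the integer-day statistics agree with the
closed forms (stabilization: x = c + d·ln(p/(1−p)) with
p(1−p) = εd/b; maximum slope b/(4d)) to <1 day and <1e−4 CC/day; the
test suite pins this.

## Mode tracking

Daily SR histograms are smoothed with a 3-bin *triangular* kernel
(0.25/0.5/0.25).  A flat boxcar — the more obvious choice — turns a
single-bin spike (a very precise rate class) into a 3-bin plateau with
no strict local maximum, so the triangular kernel is used instead.
Strict local maxima with height ≥5% of the day's tallest smoothed bin
count as peaks, including support-edge bins (the support is padded with
zeros), and peak positions are refined by parabolic interpolation,
clamped to half a bin.  Peaks are linked across days by nearest-rate
continuity with a 3 Hz/day jump limit; the three longest tracks are
kept and each is summarized by a logistic fit whose asymptote a+b is
the crystallized rate (mean of the last 7 tracked days when the fit is
unusable).  Half-bin quantization limits accuracy to roughly ±0.3 Hz
for very narrow modes.

## Deterioration, recovery, and cross-treatment similarity

Deterioration = mean CC(last 7 singing days, treatment 1) − mean
CC(first 2 singing days, treatment 2); recovery is the within-treatment-2
counterpart.  Cross-treatment similarity correlates the two 7-day
averaged stable patterns (`cc_t1xt2`) against the within-treatment
baseline `cc_t1xt1`, the mean CC of the six consecutive-day pairs in
the first treatment's stable week; a variant averaging all 49 daywise
cross CCs is also emitted because the averaged-pattern and daywise
definitions are both defensible.

Feature classification: a feature counts as deteriorating when its
cohort deterioration exceeds zero (two-sided one-sample t, α = 0.05)
*and* the mean drop is ≥0.05 CC units — a statistically detectable but
smaller drop is within the day-to-day wobble of stable-song histograms
and carries no behavioral meaning.

## Syllable distance and syntax

Each syllable is a point in (SR, d, i, FM, AM, BW, MF, E) space, each
coordinate divided by its global median over all syllables of all birds
(so rescaling any raw feature cancels).  Syllables missing a coordinate
(bout-final, hence no SR) are excluded before any distance is formed.
Per type, 100 syllables are sampled without replacement (seeded) from
the stable windows of each treatment; T1×T1 averages all distinct pairs
within the treatment-1 sample, T1×T2 all same-type cross pairs, and
T1×T2ext pairs against every *other* type's treatment-2 sample.  Types
whose modal phrase length is 1 and whose tokens sit between two
distinct phrases are treated as transitional connectors and excluded
(an explicit exclusion list overrides this heuristic).  Bird-level
means feed a one-way ANOVA with Tukey HSD across the three categories.

Syntax works on run-length-collapsed phrase sequences per bout; only
within-bout adjacent pairs count (no boundary pseudo-states).  Possible
transitions number k(k−1) for k types, since self-transitions cannot
survive collapsing.  Consistency uses a 5% commonness cutoff on the
per-bird, per-period distribution; entropy is −Σ Tᵢ log₂ Tᵢ bits.
Syntax metrics are computed over each treatment's stable week, which at
default production rates yields several hundred transitions per bird.

## Group statistics

The bird is the unit of analysis: within-bird replicates are averaged
first.  All tests are two-sided at α = 0.05.  Wrappers delegate to
scipy (paired/one-sample t, one-way F, Tukey HSD, Dunnett); Dunnett
p-values involve randomized integration of a multivariate t and are
pinned with a fixed internal seed so reports are reproducible.
Zero-variance inputs are flagged degenerate rather than producing
p-values.  Under simulated exchangeable nulls each test's empirical
type-I error calibrates to the nominal 5% (checked at 1000 replicates).

## Synthetic ontogenies

The generator emulates the statistical structure the analysis assumes,
with defaults chosen to match the study conditions the pipeline is
built for:

* 6 syllable types in three rate classes; crystallized periods d+i of
  46.08/84.03/204.08 ms give 21.7/11.9/4.9 Hz; subsong starts
  undifferentiated near 10.3 Hz (d = 55 ms, i = 42 ms).
* Phases of 200 (T1+), 75 (T1−), 35 (T2+) days with a 3-day first-song
  latency after each implant.
* Each feature's per-type mean drifts logistically from a shared
  subsong start to its target; first-treatment inflections/scales (in
  days): d 95/14, i 45/9, FM 75/12, AM 70/12, BW 70/11, MF 65/11,
  E 70/12 — chosen so the *measured* stabilization times land near the
  months-long first-treatment values quoted above (duration slowest,
  pause fastest, spectral features in between).
* **Savings** is modeled as time compression: in the second treatment
  both inflection and scale divide by `savings_factor` (default 7).
* **Selective deterioration**: at the second implant the means of i,
  FM and AM (and hence derived SR) reset 60% of the way back toward
  subsong; d, BW, MF and E resume at target.
* Per-syllable values add a day-level offset (one draw per day and
  feature, shared by all of that day's syllables — recording/motivation
  drift) of roughly 10–15% of the within-type SD, plus independent
  Gaussian noise.
* Markov phrase syntax with no self-transitions (each type advances to
  its successor with p = 0.75 or skips one with p = 0.25), per-type
  phrase lengths (fast types trill longer), ~30 bouts/day of ~5
  phrases: ≈800 syllables/day, ≈2×10⁵ per bird — about 1/30 of the
  daily output of a real recording season, which keeps a 6-bird cohort
  analysis near 20 s while leaving daily histograms dense.

The savings factor is recovered by pooling per-bird T1/T2
stabilization-day ratios over the deteriorating primitive features
(i, FM, AM).  SR is excluded from this estimator: its first-treatment
timing is dominated by the slowly developing (but non-deteriorating)
syllable duration, so its ratio confounds savings with the
duration/pause timescale difference.  The ε-threshold in the
stabilization rule is *not* scaled with the compression, which biases
single-feature ratios slightly below the true factor at high
compression; pooling over features keeps the cohort estimate within
±20% for factors 3–10 (verified in the acceptance suite).

What the generator does **not** emulate: real spectral correlations
between features, heavy-tailed or multimodal within-type variation,
annual repertoire rearrangement, circadian structure within days, or
recording dropout.  Passing tests therefore demonstrate that the
estimators recover the generative structure they assume, not that real
recordings satisfy those assumptions.

A companion fixture generator produces dendrite-segment tables
(synthetic stand-ins for traced microscopy data): per ROI a Poisson
(1.5) number of spinous segments with lognormal spine densities whose
group means (HVC: 0.95, 0.64, 0.69 µm⁻¹ for control/treated/withdrawn;
RA: no group differences) and dense-dendrite (>0.8 µm⁻¹) rates mirror
the study conditions; spine counts are Poisson(density × length), which
is why the lognormal sigmas are narrower than the target spread.

## Morphometry

Spine density is count/length per traced segment.  Group means average
birds after averaging segments within bird (the animal is the unit; a
segment-pooled variant is also reported).  The density distribution
bins segments into left-closed 0.2 µm⁻¹ classes with an open top bin
(≥1.8) and reports both dendrites-per-ROI and normalized probabilities;
the dense-dendrite statistic aggregates bins at and above 0.8 µm⁻¹.

## Numerical choices and degenerate inputs

Logistic exponents are clipped at ±500; fits use tolerances of 1e−13
and at most 2000 function evaluations per start.  Stabilization-day
search warm-starts from the closed-form derivative solution and scans
integer days.  Empty histograms, all-singleton phrase corpora,
zero-variance samples, and missing windows all yield explicit flags or
NaNs, never silent zeros.  Reports serialize NaN as null.

## Problem sizes

Unit tests run on ~20k-syllable ontogenies (80/10/25-day phases, 8
bouts/day, drift compressed 0.35×).  The acceptance suite runs 6-bird
cohorts at the full default scale for savings factors 3, 7 and 10, one
full-scale bird for rate-class recovery, and 1000-replicate null
calibrations; the whole suite completes in a few minutes on one CPU.
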