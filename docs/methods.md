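# Methods

This note records the models, conventions, and numerical choices behind
`reachtrace`, in the order a dataset flows through the package.

## Data model

A dataset couples a trial table (one row per trial, unique `trial_id`) with
named trajectory representations stored as `(trial, point, feature)` float
arrays, NaN-padded beyond each trial's valid length. Padding is never zero
(zero is a legal coordinate). Every operation returns a new container and
appends one provenance record; timestamps are shifted at import so each
trial starts at 0 ms, with the original offsets kept in provenance.
Coordinates are mathematical y-up; importers accept `screen_y_down=True`
for screen conventions. Wide-format columns follow the `prefix_index`
dialect with 1-based indices. Duplicate timestamps within a trial keep the
first row (logged); there is no principled way to choose between
simultaneous samples, so the convention is deterministic rather than clever.

## Preprocessing

Mirroring (`remap_symmetric`) decides a trial's side from the x sign of its
last point relative to its first; an exact tie counts as already on the
target side, without flipping. All interpolation is piecewise linear:
time normalization places `n_steps` (default 101, the field's convention)
temporally equidistant points; length normalization places `n_points`
(default 20) points at equal arc length along the x/y polyline, carrying
timestamps by interpolation in arc length; constant-interval resampling
reconstructs a fixed-rate recording. Endpoints are preserved exactly.

Two facts about length normalization matter for interpretation: output
points sit at exactly equal *arc* positions on the input path (the tested
invariant), but the chord lengths between output points are equal only for
locally straight paths; and the resampled polyline's total length matches
the original to well under 0.5% for smooth reach-like paths, while paths
with genuine corners (discrete changes of mind) can lose noticeably more at
20 points — a property of the resolution, not an error.

## Kinematics and trial-level indices

Velocity is unsigned speed (px/ms) from finite differences; acceleration
uses forward differences of velocity, so the first and last samples are
undefined. The movement angle `angle_v` is measured against the vertical,
positive toward negative x (the chosen side after left-remapping), in
(−π, π]; `angle_p` is the interior angle at each point (π = straight
continuation).

Curvature indices measure signed perpendicular deviation from the
idealized trajectory — the straight segment from a trial's first to last
point — positive toward the nonchosen side (positive x after
left-remapping; a trial ending straight above its start uses the same
positive-x convention). MAD keeps the sign of the absolutely largest
deviation (earliest point on ties); AUC is the shoelace area of the closed
polygon formed by the trajectory and the reversed ideal segment, with
opposite-side area subtracted. Deviations are evaluated at recorded points
only, on whatever representation is passed (raw by default).

Flips count sign alternations of successive coordinate deltas after
discarding deltas at or below `flip_threshold` (default 0 px); zero deltas
never count. Reversals count strict sign changes of x relative to the
trial's start x, skipping exact touches. Temporal indices partition
response time: movement time is the summed duration of intervals with
displacement above `jitter_tolerance` (default 0), idle time the
remainder, and initiation time the timestamp of the last still sample
before the first displacement (the idle span before movement onset; the
first-moved-sample variant is available via `initiation_at_movement`).

Sample entropy uses template length m = 3, lag 1, Chebyshev distance, and
r = 0.2 × SD of the series, computed by default on the x positions of
time-normalized trajectories. Both match counts (lengths m and m + 1) run
over the same template start indices, which makes strictly periodic series
score exactly 0. These are the standard literature choices for movement
series.

## Homogeneity diagnostics

The bimodality coefficient uses bias-corrected sample skewness and excess
kurtosis with the finite-sample correction term `3(n−1)²/((n−2)(n−3))`;
the conventional 5/9 reference is reported in documentation but never
auto-applied.

The dip statistic is computed exactly per its definition: the minimal
sup-norm distance between the empirical CDF and any unimodal
(convex-then-concave) CDF. For each candidate mode the tolerance
decomposes into flank terms — half the largest gap between the ECDF's
upper steps and the greatest convex minorant of its lower steps on the
prefix (mirror image with the least concave majorant on the suffix) — plus
a junction term coupling the two pieces through their shared value at the
mode, solved by Newton iteration on a convex piecewise-linear gap. The
implementation was validated against an independent linear-programming
encoding of the definition (exact agreement on hundreds of small random
samples; the LP lives in the test suite as a permanent oracle). Values are
floored at 1/(2n); ties are genuine atoms, so heavily tied samples dip
high, and an all-identical sample returns the floor by convention. The dip
is invariant under affine transforms and reflection but — contrary to
occasional folklore — *not* under general monotone transforms, which
reshape convexity; the tests assert the former only. The bootstrap p-value
draws uniform(0,1) null samples of the same size (seeded).

Density grids bin arc-length-uniform resampled points (step ≤ one cell) so
line coverage rather than sampling rate drives intensity; Gaussian
smoothing uses reflected boundaries, which conserves total mass.
Difference maps subtract unit-mass-normalized grids, optionally quantized
to `n_shades` signed levels.

## Type-based analysis

The trajectory distance is the summed pointwise Euclidean distance over a
common number of points (length-normalized, 20 by default). Bottom-up
typing applies the Lance–Williams Ward recursion to these distances as
given; since scipy's `ward` treats its input as Euclidean distances and
recurs on their squares, the package passes the square roots, which
reproduces that recursion exactly. Cluster labels are ordered by
descending size, and each trial's distance is measured to its cluster's
pointwise mean trajectory.

The canonical prototype set lives in a unit space from the start (0, 0) to
the chosen option (−1, 1.5), nonchosen side positive x: straight (a
segment), curved (a quadratic arc through (+0.25, 0.75)), continuous
change of mind (a smooth sweep through (+0.6, 0.9)), discrete change of
mind (straight to (+1, 1.5), then across), and double change of mind
(toward chosen, back to (+0.7, 1.3), then across). The exact vertices are
this package's own canonical choice — no published coordinate set exists —
and every consumer accepts a custom `PrototypeSet`. Ranks 1–5 order the
prototypes by implied response competition for ordinal exports. For
mapping, each prototype's control polyline is rescaled per trial by the
per-axis affine map sending unit start/end to the trial's start/end
(corners survive exactly), then both curves are length-normalized and
compared; ties go to the lower rank. Statistical comparison of type
frequencies uses the Pearson chi-square without continuity correction —
its residuals satisfy `Σ residuals² = chi2` identically — and model
fitting beyond that (mixed, ordinal) is deliberately delegated: the
package exports tidy tables instead.

## Temporal dynamics

Per-step inference regresses a feature (x position, angle, …) on
trial-level predictors at each of the 101 normalized steps, with CR1
cluster-robust standard errors by subject and t reference with G − 1
degrees of freedom. This is a deliberate substitution for per-step mixed
models, which are fragile under step-wise multiple testing; users wanting
the full mixed model export the data instead. The scan is vectorized
across steps and verified against statsmodels' cluster-robust OLS.

Consecutive-significance screening (default `min_run` 10 of 101) is
provided but should be read with care: the per-step type-I rate is
calibrated (verified over 200 seeded null replicates), yet neighboring
steps of smooth trajectories are correlated near 0.99, so null false
positives arrive in clusters and run screening does not inherit per-step
error control — about a fifth of null replicates contain a ≥ 10-step run.
This is precisely why joint models remain the only fully principled
treatment; the run screen is a descriptive device.

RT-stratified reanalysis bins trials at (0, b₁], (b₁, b₂], …, dropping
trials above the last break (default breaks 1500/2500/5000 ms). Per-type
kinematic profiles crop each trial's leading and trailing stationary runs,
compute velocity/acceleration, time-normalize to 101 steps, and smooth
with a Gaussian (SD 2 steps, reflected boundaries; SD 0 disables).

## Synthetic data generator

The generator emulates a 60-subject, 19-trial two-option categorization
design: start at (0, 0), response boxes at (±665, 974) px, 10-ms sampling
with ±0.5 ms jitter, per-condition type mixtures taken from the published
frequency table's counts (typical 506/116/54/52/16 of 744; atypical
165/38/37/56/24 of 320 — the printed rounded percentages sum to 102%, so
the counts are used), and a 6.7% error-flag rate. Each trial samples a
type, scales its prototype polyline to the layout, and traverses each
ballistic segment with a minimum-jerk speed profile; discrete types get
one submovement per leg with lognormal pauses (median 200 ms) between.
Initiation idle (lognormal, median 250 ms) precedes movement. Submovement
durations are lognormal with median 600 ms + 0.5 ms/px of path length, so
change-of-mind paths take longer — reproducing the empirical pattern that
condition RT medians sit near 1.5 vs 2 s and that change-of-mind types
occupy the upper response-time strata. Trials are clipped to the 72–2159
sample range of 100-Hz recordings, and half end on the right (mirrored)
before analysis remaps them.

Noise is i.i.d. Gaussian motor noise (default 1 px) applied to moving
samples only, with integer-pixel quantization: an optical device at rest
reports a stable integer position, and modeling it otherwise floods the
complexity indices with sensor-like flips (~90 per trial) never seen in
real 100-Hz cursor data. What the generator does *not* emulate: genuinely
autocorrelated motor noise, curved submovement corrections, item effects,
within-subject speed/accuracy trade-offs, or any cognitive dynamics —
types are drawn i.i.d. from the condition mixture. Tests passing on this
generator therefore certify the *analysis machinery* (geometry, counting,
calibration, recovery), not any claim about real hands.

`inject_step_effect` adds a condition-dependent shift to a feature inside
a 1-based step window of a time-normalized representation, recording the
window in the ground truth — the oracle used for the temporal tests.

## Problem sizes used in the test and acceptance runs

Index oracles run on 1000 randomized trajectories; type recovery uses a
seeded 513-trial balanced five-type mixture at 0.5 px noise (mapping
recovery and Ward/truth adjusted agreement); type-I calibration uses 200
seeded null replicates of 16-subject datasets; dip/normal separation uses
200 seeded sample pairs at n = 500; the generator-mixture detectability
check uses 30 seeded 56-subject datasets. These sizes give comfortable
statistical margins for every asserted bound while keeping a full run in
the low minutes on one CPU.

## Known limitations

- The prototype vertex coordinates are canonical to this package;
  borderline assignments on real data may differ from other
  implementations of the same idea.
- The dip's junction Newton solve is exact for the piecewise-linear gap
  but relies on the flank decomposition; the LP oracle in the tests guards
  this construction.
- Per-step tests assume trial-level exchangeability within subject;
  temporal autocorrelation across steps is not modeled (see above).
- `sample_entropy` is O(n²) in series length; it is intended for
  time-normalized series (~101 points), not multi-thousand-sample raw
  trials.
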