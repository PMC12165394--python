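# Methods

`pdgait` implements the computational path from 3-D kinematic time series to
motor-cognitive statistics for Parkinson-disease gait studies: segmentation
of the Timed Up and Go (TUG) test into seven timed phases from the
whole-body center-of-mass (COM) trajectory, extraction of a
spatiotemporal/kinematic panel from overground walking trials, and a
normality-gated correlation / regression / MANOVA battery relating those
gait outcomes to cognitive test scores. Because study recordings of this
kind are rarely deposited, the package ships first-class synthetic
generators whose outputs carry closed-form ground truth; every analysis
stage is validated against that truth.

## Coordinate conventions and smoothing

Trials are sampled at 120 Hz with x the direction of travel, y mediolateral
and z vertical, all in metres. All event detection runs on low-pass
filtered series. The biomechanics-standard smoother for optical data is a
generalized cross-validated quintic spline; when the cutoff is pinned (12 Hz
here) the cross-validation criterion is inert, so the default filter is the
reproducible equivalent: a 4th-order Butterworth at 12 Hz applied
forward-backward (zero phase), with reflective padding of one cutoff period
at each end to suppress endpoint transients. A GCV smoothing spline remains
selectable (`FilterSpec(method="spline")`). The passband (below cutoff/3)
is preserved within 1 % and peak times are not displaced — properties the
test suite checks directly. NaN gaps up to 0.1 s are linearly interpolated
before filtering; longer gaps are an error.

"Starting" positions referenced by the TUG rules are means over the first
0.5 s of the trial (configurable); a trial must therefore begin with at
least that much quiet sitting.

## TUG phase segmentation

Eight event markers are detected from the filtered COM x and z series:

| event          | rule                                                    |
|----------------|---------------------------------------------------------|
| stand_init     | z exceeds the seated baseline + noise tolerance (5 mm)  |
| stand_end      | first local maximum of z after stand_init               |
| gait_init_end  | x − start_x > 1 m                                       |
| turn_begin     | x − start_x > 3 m                                       |
| turn_end       | first later time x − start_x < 3 m                      |
| walk2_end      | first later time x − start_x < 1 m                      |
| sit_begin      | z < 95 % of standing height                             |
| sit_end        | first later time x ≤ start_x                            |

The seven phase durations telescope between consecutive events
(sit-to-stand, gait initiation, walk 1, turn, walk 2, slow down & turn, sit
down), so they partition [stand_init, sit_end] exactly; this is the only
ordering-consistent assignment of eight markers to seven contiguous phases.

Numerical choices:

* Threshold crossings are located by linear interpolation between the
  bracketing frames and reported at **sub-frame resolution**. Rounding
  events to the nearest frame would add up to ±½ frame per event, i.e. up
  to a full frame per phase duration from rounding alone, which would
  consume the entire segmentation error budget before any signal error.
* `stand_end` ("first maximum peak") uses a prominence guard (the 5 mm
  noise tolerance) against noise peaks and is refined by a local quadratic
  least-squares fit over ±0.125 s, which suppresses the peak-position
  jitter that raw argmax exhibits under marker noise.
* The downward crossings (turn_end, walk2_end) are searched after the
  excursion apex, making them robust to filter ripple near the 3 m
  tangency.
* `stand_init` uses baseline + 5 mm rather than a strict inequality so the
  rule is meaningful on noisy data; the tolerance is configurable.
* The sit threshold is anchored to **absolute** standing height (95 % of
  the z value at stand_end), exactly as the rule is stated; consequently
  detection is invariant to horizontal translation but not to adding a
  constant to z. A vertical offset moves `sit_begin` only.
* If `x ≤ start_x` never fires after sit_begin (sitting placement slightly
  forward of the chair), the time of the x-minimum after sit_begin is used
  and the fallback is logged.

A rule that cannot fire raises an error naming the event and the closest
approach (e.g. `turn_begin not reached: max excursion 2.5 m`). Repeated
TUG trials are combined by the per-phase arithmetic mean.

## Walking metrics

Foot events use the coordinate-based family standard for optical gait data:
per side, foot strikes are local maxima of (heel_x − COM_x) and foot offs
are local minima of (toe_x − COM_x), with a minimum peak separation of
0.6 s and prominence of 1 cm; one foot-off must fall between consecutive
same-side strikes (alternation), and extremum times are refined by
three-point parabolic interpolation.

* **Velocity** — zone length divided by the time the COM takes to cross a
  3.3 m capture zone centered (by default) on the midpoint of the traversed
  range, with sub-frame crossing times. A COM-displacement/time variant is
  available (`velocity_mode="com_displacement"`); the two agree whenever
  the zone is traversed monotonically, which is also enforced.
* **Stride length** — anterior heel displacement between consecutive
  same-side strikes, averaged over all strides of both sides.
* **Double support** — per stride, the sum of the two double-limb
  intervals (ipsilateral strike → contralateral off, contralateral strike →
  ipsilateral off), averaged across strides; this total-per-stride
  definition matches the magnitude of published cohort values (~0.34 s).
  Interval bounds are inclusive so perfectly anti-phase events yield 0.
* **Minimum toe clearance** — per swing (off → next same-side strike), the
  minimum of filtered toe height above the floor reference within the
  middle 80 % of swing (trimming avoids boundary artifacts), averaged per
  side. The default floor reference is the **median of filtered toe height
  over the central 60 % of detected stance intervals**: the stance plateau
  is flat, so this estimator is unbiased under noise, whereas the trial
  minimum (also selectable as `floor_mode="min"`, or a constant) is biased
  low by roughly the filtered noise extreme (~2–3 mm at σ = 2 mm) — larger
  than the clearance error budget itself.
* **Joint range of motion** — rotation matrices are decomposed with the
  XYZ Cardan sequence (R = Rx·Ry·Rz; the first angle is flexion-extension
  under the joint coordinate system convention), continuity-unwrapped, with
  gimbal proximity (|β| > 89°) logged. ROM is max − min of the
  flexion-extension angle per gait cycle (strike to same-side strike),
  averaged across cycles. Other planes are computed but unreported.
* **Shoulder symmetry angle** — θ = arctan(left/right);
  SA = (45° − θ)/90° × 100, with the 180° wrap for out-of-range θ. The
  magnitude is tabulated (published asymmetries are non-negative); the
  signed value, which is antisymmetric under side swap, is retained.
* **Impaired-side rule** — toe clearance and hip ROM enter analysis from
  the clinically impaired side; bilateral or no impairment uses the
  across-side mean. `impaired_side` is consumed as metadata.

Two trials per condition are averaged element-wise; a trial missing a
metric contributes nothing to that metric's average (logged).

## Statistical battery

The battery mirrors the field's standard pipeline on a cohort table of 3
cognitive scores (response inhibition, working memory, mental rotation), 7
TUG phase times, and 6 + 6 single-/dual-task walking metrics:

1. **Normality** — Shapiro-Wilk per variable (scipy's Royston
   approximation), normal iff p > α (default 0.05).
2. **Correlations** — all 3 × 19 cognitive-gait pairs. Pearson when *both*
   members are normal, Spearman otherwise (the conservative reading of a
   normality-gated choice). 95 % CIs by Fisher z: SE = 1/√(n−3) for
   Pearson, the Fieller-corrected √(1.06/(n−3)) for Spearman. Spearman
   p-values use the t approximation. No multiplicity correction by default
   (a Benjamini-Hochberg flag exists, off). Pairwise-complete missing-data
   handling; a failing pair is recorded as a flagged row, not an abort.
3. **OLS** — each gait metric on the three cognitive scores plus intercept
   (statsmodels; df = n − 4), reporting B, SE, t, p, 95 % CI, R², adjusted
   R²; listwise deletion; rank deficiency is an error naming the collinear
   columns.
4. **MANOVA** — per response block (TUG phases, single-task metrics,
   dual-task metrics), a multivariate linear model with one single-df test
   per term from the eigenvalues of H E⁻¹ (hypothesis vs error SSCP):
   Wilks' Λ = Π 1/(1+λ), Pillai's trace = Σ λ/(1+λ), Hotelling-Lawley
   trace = Σ λ, Roy's greatest root = λ_max, with Rao's F for Wilks, the
   Pillai-trace F, the classical Hotelling-Lawley F, and an upper-bound F
   for Roy. For a one-df hypothesis all four reduce to the same
   F(p, v−p+1); with a single response Wilks' Λ = 1 − R² exactly. Both
   identities, and agreement with an independent reference implementation,
   are asserted in the tests. MANOVA tables are written in the standard
   (value, F, num df, den df, p) column order.
5. **VIF** — 1/(1−R²) of each predictor regressed on the others; perfect
   collinearity reported as infinite.

Report files (TSV per table plus a JSON bundle) are byte-stable for
identical inputs.

## Synthetic data

The generators are built for exact ground truth rather than biomechanical
realism; every one is seed-deterministic (bitwise identical repeats).

**TUG trajectories.** COM z rises from the seated height through a
half-cosine to a standing peak, with a small overshoot whose decay
curvature is matched to the rise curvature so the peak is locally
symmetric (keeping quadratic peak refinement unbiased), then descends
through a cosine whose 95 %-threshold crossing is solved to land exactly on
the programmed sit_begin. COM x is a monotone PCHIP through knots placed at
the programmed 1 m/3 m crossing times, so the excursion rules fire exactly
at the knots; after sit_end the COM keeps drifting slightly backward so the
final crossing has a firm slope (a flat tail makes sit_end timing
noise-fragile). Emitted ground-truth events are the analytic rule-crossing
times, including the stand-initiation tolerance crossing. Defaults follow
the published cohort phase means (1.13, 0.59, 1.73, 2.98, 1.89, 1.32,
1.33 s), seated/standing COM heights of 0.55/0.95 m, and a 1 s seated
lead-in. Infeasible programs (e.g. a walk-1 phase too short to span the
1 m → 3 m excursion at a plausible speed) are rejected.

**Walking trials.** COM x advances uniformly at the programmed velocity
over ≥ 15 m (≥ 5 m of lead-in before the capture zone); heel and toe
anterior positions oscillate sinusoidally about the COM at the stride
frequency f = v/SL with anti-phase sides, so strike/off times, stride
length and double support have closed forms (the toe phase lag is chosen so
foot-off trails the contralateral strike by exactly half the programmed
double-support time). Toe height is zero in stance and follows a quartic in
swing whose interior minimum at mid-swing is the programmed clearance, with
lift peaks near 17 %/83 % of swing. Hip and shoulder flexion are sinusoids
with the programmed ROMs, composed into XYZ rotation matrices. Marker noise
is additive i.i.d. Gaussian on positions only (not rotations). Defaults
follow the published single-task cohort means (v = 1.32 m/s, SL = 1.36 m,
DS = 0.34 s, TC = 0.034 m, hip ROM ≈ 50°).

**Cohorts.** A Gaussian copula: a multivariate normal draw with a target
latent correlation matrix is pushed through per-column marginal transforms.
Normal columns are affine; columns that are non-normal in the published
cohort (response inhibition, TUG sit-down, both shoulder asymmetries,
dual-task double support) use a shifted (3-parameter) lognormal matched to
the published mean and SD with target skewness = max(2-parameter implied
skewness, 1.5). The floor matters: the published mean/SD of dual-task
double support imply a 2-parameter lognormal skewness of only ~0.38, too
mild to fail normality checks reliably at n = 19; the floor makes the
Spearman gate engage in ≥ 95 % of study-sized draws without disturbing the
first two moments. The default correlation targets embed the published
cognitive-by-TUG and cognitive-by-dual-task coefficients with all other
off-diagonals zero; that matrix is far from positive semi-definite (the
published gait metrics were mutually correlated, which the zeros discard),
so it is repaired to the nearest correlation matrix (Higham projection,
cached), the repair is logged, and the **repaired** matrix is returned as
the generating truth. Targeted experiments that need exact correlations
(e.g. ρ = 0.65 between working memory and dual-task velocity) should pass a
small PSD target matrix, which is used verbatim.

What the generators do not emulate: stride-time and stride-length
variability, asymmetric or festinating gait, turning kinematics inside
walking trials, soft-tissue/marker-model artifacts, and any dependence of
the waveforms on cognitive load. Passing recovery tests therefore
demonstrates correctness of the detectors and statistics on well-formed
signals with realistic noise amplitude, not robustness to pathological
gait.

## Problem sizes and tolerances

The validation suite uses 200 TUG trials per noise regime (noise-free
recovery within 1 frame ≈ 8.3 ms; σ = 2 mm recovery within 25 ms in ≥ 95 %
of trials), 100 walking trials at σ = 2 mm (median recovery error ≤ 2 %
per metric, ≤ 2 mm for toe clearance), 10⁵ random rotations for the Cardan
round trip (< 1e-9°), 1000 null cohorts at n = 19 for type-I calibration
(per-test rejection within [3.5 %, 6.5 %] at α = 0.05), and 1000 study-sized
cohorts for CI coverage (within [92 %, 98 %]). These sizes make the whole
suite run in a few minutes on a single CPU while keeping the Monte-Carlo
error of each rate well inside its acceptance band.

## Known limitations

* The TUG detector assumes one out-and-back excursion; multiple turns or
  freezing episodes are out of scope.
* Toe-clearance's stance-median floor assumes a locally flat stance toe
  height; strong forefoot rocker motion would bias it (the `min` and
  `constant` floor modes exist for such data).
* The Fisher-z CI for Spearman is an approximation; exact permutation CIs
  are not implemented.
* Roy's greatest root F is an upper bound (flagged by convention), not an
  exact test.
* C3D ingestion is not implemented; trials are consumed from the documented
  CSV dialect.
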