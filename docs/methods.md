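# Methods

`swimphase` evaluates a swimmer's performance over a single 25 m lap from
one sacrum-worn 6-axis IMU (500 Hz accelerometer + gyroscope), mirroring
the workflow used in wearable swimming biomechanics: express the inertial
signals in the pool frame, split the lap into the four wall-to-wall
phases — wall push-off (*Push*), glide (*Glid*), stroke preparation
(*StPr*) and swimming (*Swim*) — extract a catalogue of phase-based
kinematic micro-variables, and relate them to reference performance
metrics (goal metrics) derived from a tethered-speedometer
velocity/displacement trace, via LASSO variable selection and
leave-one-out cross-validated regression.

## Coordinate frames and orientation

Three frames are used:

* **sensor** — the device axes as mounted;
* **anatomical** — body axes: `x` anterior–posterior, `y` longitudinal
  (cranial positive), `z` mediolateral;
* **global** — pool axes: `X` lateral, `Y` swimming direction, `Z`
  vertical up.

Calibration applies `v ← R · S · (v − bias)` per sensor (offset, scale /
non-orthogonality, then the sensor→anatomical rotation). The functional
rotation is estimated from two on-land movements: the mean specific-force
direction while standing upright gives the longitudinal axis; the
dominant gyroscope axis during squats, orthogonalized against it, gives
the mediolateral axis; the anterior–posterior axis completes the
right-handed triad. Intrinsic calibration parameters (bias, scale) are
*applied*, not estimated — estimating them needs a multi-position
protocol that is out of scope.

The identity orientation is defined as the **streamlined glide posture**
(prone, facing the far wall): there the anatomical axes coincide with the
pool axes. This choice matters: the package's Euler-angle convention
(yaw ψ, roll θ, pitch φ, computed from the quaternion by closed-form
atan2/arcsine expressions) has its arcsine singularity exactly at the
90° pitch that separates an upright reference from a prone swimmer, so
anchoring the identity at the swimming posture keeps every angle far
from gimbal lock throughout a lap. The printed angle formulas equal the
Z-Y-X factorization of the conjugate quaternion; their exact inverse is
implemented, and round-trip identity (1e−9, componentwise) is enforced
by tests away from the singularity. Angle signs follow the formulas as
written (a positive single-axis body rotation yields a negative angle);
all downstream statistics are sign-agnostic (means, ranges, standard
deviations, linear models).

Orientation over time comes from a gradient-descent complementary
filter of the Madgwick IMU type: the quaternion is propagated by the
exact exponential-map gyroscope step and corrected toward the measured
gravity direction by a normalized-gradient step of size β·dt
(default β = 0.1 rad/s). Two deliberate additions:

* **Acceleration gating** (default ±0.5 m/s² around g): the correction
  is skipped when the specific-force magnitude is inconsistent with
  quasi-static gravity. The push burst (several m/s² of forward
  acceleration) would otherwise drag the attitude several degrees off.
  Gating cannot detect *horizontal* accelerations (they barely change
  the magnitude), so a residual "tilt illusion" of a few degrees remains
  during the glide deceleration; this is a fundamental identifiability
  limit of accelerometer-aided attitude, not an implementation artifact.
* **Exponential-map integration**: the first-order Euler quaternion
  update drifts ≈ (|ω|Δt)²/8 per step; at stroke-rate angular velocities
  (≈2 rad/s) and 500 Hz that is ~0.06°/s — irrelevant for angles, but
  ruinous once orientation errors are integrated twice into
  displacement.

The initial quaternion is the minimal rotation aligning the mean
accelerometer direction of the pre-lap quasi-static window (≈5 s in the
water) with global up; minimal rotations carry no vertical twist, so
initial yaw is zero by construction — the pool's swimming direction is
the yaw reference (no magnetometer is usable under water).

Global-frame signals are `Acc_G = q ⊗ [0, Acc_A] ⊗ q*` (likewise for the
gyroscope), with gravity subtracted from the vertical channel so that
AccX/AccY/AccZ are motion accelerations; the efficiency ratios on AccY
would be meaningless with gravity leakage.

## Phase segmentation

The lap is bracketed by quasi-static spans. The lap start is the onset
of the forward-acceleration push burst (≥1.5 m/s² sustained ≥50 ms,
walked back to the preceding near-zero sample); the lap end is the end
of the sustained gyroscope-activity region after the burst (the swimmer
stops rolling and kicking at wall touch, while the accelerometer still
sees the final deceleration, so the gyro envelope is the cleaner end
marker). Interior boundaries:

* **Push → Glid**: the zero-crossing of the smoothed forward
  acceleration after the burst peak, accepted only when followed by
  sustained deceleration with no rebound — braking ripples inside the
  burst must not end the phase.
* **Glid → StPr**: the 1–4 Hz band envelope of the mediolateral
  gyroscope rising above max(√5 × gliding baseline, 30% of its
  post-push amplitude), backtracked to the oscillation foot.
* **StPr → Swim**: the stroke-cycle channel envelope rising to 50% of
  its steady swimming amplitude, backtracked to a floor of 35% — the
  floor sits above the kick amplitude so the walk stops at the
  kick/stroke transition when both share the mediolateral channel
  (breaststroke, butterfly). This envelope onset approximates the first
  stroke peak without the quarter-period bias a literal first-peak read
  would carry.

Intervals are half-open `[on, off)` so durations and sample memberships
are unambiguous at 500 Hz; the four phases partition the lap exactly
(enforced invariant). Camera-style annotations, when provided, bypass
the detector after invariant checks — the reference path. Thresholds are
config parameters; the defaults are justified on the simulator only, as
no real recordings ship with the package.

Stroke cycles are successive positive peaks of the anatomical
longitudinal angular velocity (GyrY) for front crawl and backstroke, or
the mediolateral one (GyrZ) for breaststroke and butterfly. The channel
is smoothed with a 0.15 s moving average (strokes are ≤ ~1.5 Hz; raw
500 Hz sensor noise otherwise produces prominence-passing spurious
peaks), then peak-picked twice: a liberal pass fixes the median
inter-peak interval, the second enforces a minimum distance of half that
interval.

## Micro-variables

Per phase (categories in parentheses): Mean/Range/SD of AccX/Y/Z and
Max/Int/Momentum of AccY (propulsion); Mean/Range/SD of the roll and
pitch angles, in degrees (posture); Eff and Eff_dir (efficiency);
Mean/Range/SD of GyrX/Y/Z and the phase duration (duration/rate). StPr
adds kick rate and count (mediolateral-gyro peaks with prominence
> 0.5 rad/s); Swim adds stroke rate and count, mean cycle duration, and
DPS. Per-cycle rows carry cycle duration, DPS, per-cycle angle and AccY
statistics and the efficiency ratios. 126 lap-level columns per
technique; the catalogue enumeration is asserted in tests.

Definitions that needed fixing beyond their names:

* **Int** = net trapezoidal ∫AccY dt over the phase (m/s); **Momentum**
  = the positive-part integral ∫max(AccY, 0) dt — the mass-normalized
  propulsive impulse. This makes Momentum ≠ Int and propulsion-specific.
* **Eff** = ∫max(AccY,0)dt / ∫max(−AccY,0)dt;
  **Eff_dir** = ∫max(AccY,0)dt / ∫‖Acc‖dt. Time integrals, not sample
  counts, so both are sampling-rate invariant. A zero denominator marks
  the variable undefined and the observation is dropped with a logged
  reason (no imputation).
* **DPS** (distance per stroke) integrates forward velocity over each
  cycle. Velocity is reconstructed by integrating global forward
  acceleration from the wall (v = 0 at lap start) on a *gyro-only
  strapdown* orientation anchored in the pre-lap static span: over a
  sub-30 s lap, gyroscope random walk is far below the gravity leak
  that accelerometer corrections introduce during the glide. The Swim
  segment is then linearly de-drifted, pivoting at the phase entry
  (where the integral is still anchored by the wall) under the
  steady-state zero-net-acceleration constraint. On simulated front
  crawl this keeps DPS within ~5% of truth; breaststroke and butterfly,
  whose large mediolateral stroke rotations couple more error into the
  forward channel, occasionally reach ~10%. A reference-trace velocity
  path is available as an alternative. Double-integration drift is the
  known failure mode of sacrum-IMU velocimetry; these anchoring choices
  are mitigations, not a solution.

## Goal metrics

Eight reference targets per lap, read from the parallax-corrected
speedometer trace within the annotated phases: Push maximum velocity
(global max in Push), Glid end velocity (interpolated at Glid.off), StPr
average velocity, the per-cycle average velocities, the Swim-phase
average velocity, the 5 m and 15 m times from the wall (linearly
interpolated crossings of the displacement), and lap average velocity
(pool length / lap time). Displacement is 0 at wall contact.

The parallax model is the right triangle: the device sits h ≈ 0.62 m
above still water; with cable length L = √(d0² + h²) + d_payout the
swimmer's horizontal distance is x = √(L² − h²) and v_forward =
v_cable·L/x. The correction factor decreases monotonically to 1 away
from the wall.

## Selection and regression

Per goal metric the design matrix is scoped to the phases that determine
it (Push for push maximum velocity, Push+Glid for T5m, Push+Glid+StPr
for T15m, all phases for lap average velocity, per-cycle variables for
the per-cycle target). Columns are z-scored (sample SD; constant columns
dropped), multicollinearity is removed by iterative VIF filtering
(VIF_j = 1/(1−R²_j), drop the largest until all < 10, ties by column
order), and LASSO selection runs on a 100-point log-spaced penalty grid
with 10-fold CV. The selection penalty uses the one-standard-error rule:
on pure-noise targets the CV-minimum rule admits several spurious
variables, while 1-SE keeps ≤2 spurious selections in ≥90% of seeds
without hurting support recovery on planted models. Relative weight of a
variable is 100·|β|/Σ|β| on the standardized design; variables under 5%
are neglected; category contributions are the summed weights of the
selected set, reported raw and renormalized to 100% (both, since either
convention is defensible). If the CV penalty zeroes everything, the
largest penalty activating at least one variable is used instead, with a
warning.

Goodness of fit is leave-one-out cross-validated: the penalty is chosen
once by 10-fold CV on the full data, then each observation is predicted
by a LASSO refit at that penalty on the remaining n−1. R² is computed on
the pooled held-out predictions (not averaged per fold), RMSE is the
root mean squared held-out error, and relative RMSE is RMSE as a percent
of the target mean. Choosing the penalty once rather than inside every
LOO fold leaves a mild optimistic bias on the penalty choice (not the
coefficients); the fully nested variant would be ~1000× slower for the
per-cycle target (~700–1200 cycles) with no visible change at the
reported precision. Coefficients below 1e−10 are treated as zero.

## Synthetic data

The simulator generates everything the pipeline consumes, with exact
ground truth. Forward velocity is piecewise: a half-cosine rise to the
push peak (default 2.5 m/s) with a zero-mean 5 Hz mid-push ripple (8% of
v_peak — real push-offs brake intermittently as the legs extend, and
without any negative AccY inside Push the Eff ratio would be undefined
there); exponential drag decay v = v_peak·e^(−kt) (k = 0.4 1/s) through
the glide; a smooth kick-modulated recovery to the steady swim velocity
(default 1.6 m/s); then cyclic swimming with 8% intra-cycle modulation
at the stroke rate (default 0.75 Hz) until the integrated displacement
reaches 25 m, followed by a stop ramp. The orientation trajectory is a
rotation-vector deviation from the glide posture: stroke-cycle roll
about the longitudinal axis (front crawl/backstroke, 0.5 rad) or
mediolateral stroke rotation (breaststroke/butterfly, 0.6 rad), StPr
kick oscillation on the mediolateral axis (0.04 rad at 2.2 Hz), and a
slow pitch posture wobble. Body rates are derived from the quaternion
trajectory by exact finite-difference logarithms; anatomical-frame
specific force is R(q)ᵀ(a_motion + g·ẑ); white Gaussian sensor noise
(accelerometer 0.05 m/s², gyroscope 0.01 rad/s) is added last. The
reference trace samples the same velocity model at 100 Hz; annotations,
cycle boundaries (positive peaks of the noise-free cycle-channel gyro)
and the eight goal metrics are computed from the generating model.

The cohort generator draws a latent per-swimmer ability (standard
normal) that coherently shifts push peak velocity (±0.18 m/s per SD),
swim velocity (±0.13 m/s), drag decay (∓0.04 1/s), stroke rate
(∝ velocity^0.7) and posture quality, with ~2% per-trial jitter; each
swimmer swims each technique at paces 0.7/0.8/0.9/1.0 of full effort
(19 swimmers × 4 paces = 76 laps per technique). A separate planted
linear generator (X ~ N(0,1), sparse β, optional collinear block)
exercises the statistical engine at known population R².

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: hydrodynamic forcing, inter-swimmer technique
style, sensor bias drift and temperature effects, soft-tissue artifact,
synchronization error between systems (exposed as a config offset but
zero in simulation), turns and dive starts. The simulator reproduces the
statistical and kinematic *structure* the pipeline assumes; results on
it validate the algorithms, not the physiology.

## Numerical choices and degenerate inputs

Quaternions are renormalized every step (unit norm enforced to 1e−9);
the Euler arcsine argument is clipped at ±1 with a warning; empty
intervals, NaN samples, non-invertible calibrations, non-static
calibration windows, degenerate squat axes (< 10° from longitudinal),
flat cycle channels and missing 15 m crossings all raise explicit
errors; a collapsed StPr (immediate stroking) is clamped to a minimal
width with a warning rather than inverting the phase order. All
randomness flows through seeded NumPy generators; rerunning any stage
with the same seed is bit-reproducible.

## Problem sizes used in validation

The test suite and the acceptance script use: 1,000 random
quaternion/vector pairs for the rotation oracle; 10,000 orientations
for the Euler round trip; 10 s tumbles for fusion; 50 laps across the
four techniques for segmentation; a 19-swimmer × 4-pace front-crawl
cohort (76 laps, ~700 cycles) for the end-to-end run; and 20–50 seeds
for the planted-model statistics. These sizes make the full suite run
in a few minutes on one CPU while keeping every statistical check
comfortably powered.

## Known limitations

* Absolute velocity from a sacrum IMU is weakly observable; DPS
  accuracy degrades for techniques with large mediolateral rotations.
* The phase detector is a heuristic stand-in for a camera-validated
  detector; its thresholds are simulator-justified defaults, and
  camera-style annotation input is the reference path.
* Yaw is defined only relative to the pre-lap posture (no magnetometer);
  any true heading change during the lap is invisible to the angles.
* The linear model family is intentional (interpretability); strongly
  non-linear kinematics–performance relations will be underfit.
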