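# Methods

`mimufuse` estimates the 3-D orientation of a magnetic/inertial measurement
unit (MIMU) from its gyroscope, accelerometer and magnetometer streams, and
quantifies the accuracy of three estimators on two synthetic benchmark
scenarios modelled on typical human-movement trials. This note documents the
models, conventions, parameter choices and known limitations.

## Frames and quaternion conventions

* **ULF** — the sensor-fixed (unit local) frame.
* **GGF** — a gravity-aligned global frame: X forward, Y right, Z down
  (gravity positive down). GGF is *defined* to coincide with ULF during the
  static posture at the start of a trial, so the initial orientation is the
  identity and all reported orientations are changes relative to the initial
  posture.

Quaternions are scalar-last `[qx, qy, qz, qw]` with the Hamilton product; the
identity is `[0, 0, 0, 1]`. An orientation quaternion is body-to-world:
`v_GGF = R(q) v_ULF`. With body rates ω (ULF, rad/s), the kinematic equation

    dq/dt = ½ Ω(ω) q = ½ q ⊗ [ω; 0],
    Ω(ω) = [[−[ω×], ω], [−ωᵀ, 0]]

propagates this body-to-world quaternion directly. The matrix and product
forms are algebraically identical under the Hamilton convention (the test
suite asserts this), and the convention is validated by the static limit: at
the identity, the synthesized accelerometer reads (0, 0, −1) g (specific
force opposing gravity) and the magnetometer reads the ambient field.

## Estimators

**INT — strapdown integration.** The discrete propagation is the exact
matrix exponential of ½Ω(ω)dt under the assumption that ω is constant within
each sampling interval (zero-order hold): a rotation of |ω|dt about ω/|ω|
composed on the body side, renormalized every step. ZOH is kept rather than
midpoint blending because it is the closed-form solution of the stated
piecewise-constant model; its discretization error for the manual-routine
rate profile at 128 samples/s is ≈0.13° over 60 s, negligible against sensor
error. A gyro static bias, if supplied, is subtracted from the whole rate
series first. The package also provides the deliberately *wrong* per-axis
cumulative trapezoid (`naive_component_integration`) to demonstrate that
integrating angular-velocity components separately does not produce an
orientation for 3-D motion.

**SF — quaternion extended Kalman filter.** State: orientation quaternion
(4), gyro bias (3, rad/s) and an additive ambient-field disturbance vector
(3, μT, GGF) with a full 10×10 covariance. Prediction propagates the
quaternion with bias-corrected rates through the exact constant-rate step;
the bias is a random walk and the disturbance a first-order Gauss–Markov
process with correlation time τ = 1 s. Process noise uses the rate-of-change
convention: a parameter quoted in unit/s contributes a per-step standard
deviation of `value·dt`. (The continuous-PSD reading `value²·dt` was
evaluated and rejected: at the locomotion preset's 10 μT/s it gives the
disturbance state a stationary spread of ≈7 μT, which makes heading
unobservable — the filter can then explain any heading drift as field
change, and the locomotion heading error grows without bound.)

Measurement updates are sequential (accelerometer, then magnetometer) with
vector selection: the accelerometer is used only when `||a|−1 g|` is inside
the acceleration gate, the magnetometer only when its magnitude matches the
reference field within the magnetic gate *and* the dip angle of the measured
field (rotated to GGF with the current attitude) matches the reference dip
within ±15° (configurable; the direction test has no published value).
Gated-out samples leave the state bit-identical to the prediction. Updates
use the Joseph-form covariance; symmetry is enforced every step and positive
semi-definiteness is probed by Cholesky with eigenvalue clipping as the
repair path. Measurement Jacobians are the analytic 3×4 derivatives of
`R(q)ᵀu` in the homogeneous quaternion parameterization, verified against
central differences.

Two parameter presets are built in (manual routine / locomotion):
gyro noise 2.5/2.5 °/s, bias walk 0/0.01 °/s², disturbance process noise
1/10 μT/s with τ = 1 s, accelerometer noise 10/2.5 mg, magnetometer noise
3/3 μT, acceleration gate 40/10 mg, magnetic gate 5/5 μT.

Initialization: orientation = identity; the reference field is the
magnetometer mean over the 5 s static prologue (a TRIAD-style init from one
accelerometer/magnetometer pair is the fallback when no static prologue is
detected). Initial covariance: 1e-4 per quaternion component, (0.1 °/s)²
bias, (5 μT)² disturbance. The bias prior is deliberately tight because
input traces are bias-corrected (residual ≲0.03 °/s); a loose prior of
(0.5 °/s)² lets rhythmic gait accelerometer residuals drag the bias state by
more than 1 °/s early in a locomotion trial, producing a large heading
transient.

Two structural limitations are worth knowing. First, a constant field offset
whose effect is indistinguishable from a yaw (a pure east-west offset) is
absorbed by the heading, not the disturbance state — only
magnitude/dip-inconsistent offsets are identifiable. Second, the Gauss–
Markov decay shrinks the equilibrium estimate of a truly constant offset to
≈70–80% of its value; the state is built for transient disturbances.

**CF — gradient-descent complementary filter.** Stateless beyond the
quaternion. Each step propagates with the gyro (same exact step as INT, so
the β = 0 limit is bit-equal to pure integration) and subtracts
β·dt·∇f/‖∇f‖, one normalized gradient-descent iteration on the stacked
objective: rotated gravity direction minus normalized specific force, and
rotated reference field minus normalized magnetic measurement. The magnetic
reference is recomputed every step from the measurement rotated into GGF
with the current estimate, flattened to `[√(hx²+hy²), 0, hz]` — the
null-east construction that confines magnetic disturbances to the heading
degree of freedom. No gating and no noise statistics are used. The gain
follows β = √(3/4)·ω̃_max with ω̃_max = 3× the gyro noise SD; the default is
the published 0.1 rad/s (= 5.73 °/s).

## Error metrics

The per-sample error quaternion is Δq̄ = reference⁻¹ ⊗ estimate, with total
angle Δθ = 2·acos(|Δq₄|) (the absolute value resolves the q/−q double
cover). For the heading/attitude split, the world-frame error rotation
`q_est ⊗ q_ref⁻¹` is factored by swing-twist about the GGF vertical: the
twist angle is the heading error (yaw discrepancy), the residual swing angle
the attitude error (roll/pitch discrepancy). Recomposition swing ⊗ twist
reproduces the error rotation exactly, and for small errors
Δθ² ≈ heading² + attitude². Accuracy per trial is the RMS of each component;
whether the 5 s prologue is included is configurable (included by default).

## Synthetic scenarios

Both generators produce orientation and body rates analytically, so the
ground truth is kinematically consistent by construction (finite-differenced
quaternions reproduce the rate series to <0.1 °/s RMS at 128 samples/s).
All randomness is driven by a single integer seed; identical inputs give
bit-identical outputs.

**Manual routine (60 s default, forearm-style).** A 5 s static prologue,
then six single-body-axis rotations (two per axis with opposite signs,
cumulative per-axis amplitude drawn from 108–132°, inside the nominal
~120°), each a C² minimum-jerk profile over 4 s followed by a ≥2 s static
pause; trailing time is static (static fraction ≈60%). Each movement carries
an oscillatory inertial-acceleration burst (peak 0.08 g, ~1.5 Hz
accelerate/decelerate cycling under a smooth envelope) in a random fixed
direction — a several-second *coherent* acceleration would be an
unrealistically adversarial input for any accelerometer-aided filter.

**Locomotion (180 s default, lower-trunk-style figure-of-eight).** After the
prologue and a 3 s ramp, heading follows 130°·sin(2πt/T_lap) (T_lap ≈ 20 s),
giving the full ≈260° excursion each lap with alternating left/right turns;
roll (2° at the ~0.9 Hz stride rate) and pitch (1° at the step rate) stay
well below 10°. The resulting vertical-to-horizontal mean |ω| ratio is
≈3.4–4.0 across seeds (nominal 3.6×). Gait inertial acceleration (0.05,
0.03, 0.10 g on ULF x, y, z at the gait frequencies) carries smooth random
amplitude and phase modulation (25% scale, ~4 s correlation) emulating
step-to-step variability; a perfectly periodic gait phase-locks the samples
accepted by the acceleration gate and produces a rectified heading error in
the EKF that real walking does not. The ambient-field variation seen along
the path is a smooth additive GGF vector with period tied to the lap and
peak ≈5 μT — small and slow enough that the filters cannot flag it as a
disturbance, which is precisely what makes locomotion heading the hardest
quantity here.

**Sensor model.** Gyro: white noise 2.5 °/s, optional constant bias and
bias random walk, plus an in-run drift term — a Gauss–Markov process
(τ = 60 s) whose per-axis SD is 1% of that axis's mean |rate| over the
trial. The rate-proportional form reflects that strapdown drift grows with
the angular-velocity amplitude of the motion (scale-factor error,
nonlinearity, g-sensitivity all scale with excitation), which is also why
drift concentrates on the vertical axis during walking (rates ~3.6× larger)
while attitude drift stays small. The 1% figure was calibrated once so that
pure integration lands in the empirically observed error range for these
tasks (heading RMS of order 1° over a 60 s manual trial and 10–30° over a
180 s figure-of-eight); white noise alone underpredicts real strapdown
drift by an order of magnitude. Accelerometer: gravity direction in ULF plus
true inertial acceleration plus 10 mg white noise (the device's noise; the
EKF locomotion preset's 2.5 mg is a tuned filter parameter, not a sensor
property). Magnetometer: per-axis sensitivity and hard-iron bias applied to
the rotated total field plus 3 μT white noise. The ambient field is 40 μT at
60° dip. Outputs are clipped to the full-scale ranges ±1500 °/s, ±6 g,
±600 μT.

**Magnet event.** A transient ferromagnetic disturbance (default 200 μT
peak, five times the ambient field) with an inverse-cube dipole profile of
the smoothly varying sensor–magnet distance (8:1 edge-to-closest ratio:
<1% of peak at the window edges, untouched outside). Its default direction
in GGF is near-vertical `(0.1, 0.05, 0.99)`: a sensor reaching over a small
magnet lying on a table passes close to the magnet's (vertical) dipole
axis, where the field points along that axis. The direction is
configurable; a strongly horizontal disturbance of this magnitude would
drag any magnetometer-aided heading while it lasts.

## Pre-processing and calibration

Resampling is cubic-spline interpolation onto a uniform grid (the
acquisition-rate-to-200-samples/s step of the standard pipeline). Low-pass
filtering is a 2nd-order zero-lag (forward–backward) Butterworth; the cutoff
can be chosen by Winter-style residual analysis — RMS residual versus
candidate cutoff, straight line fitted to the noise-dominated upper half of
the candidate range, cutoff = the lowest candidate whose residual falls
below the line's zero-frequency intercept. Gyro static bias is the per-axis
mean over a verified-static acquisition (per-axis SD ≤ 3× the nominal noise
SD, else the trace is rejected as motion-contaminated). The accelerometer
check compares per-axis means of three gravity-aligned static postures to
±1 g/0 and flags deviations above 0.02 m/s². Magnetometer calibration fits
an axis-aligned ellipsoid (Σ A_i m_i² + Σ D_i m_i = 1) by linear least
squares; center → hard-iron bias, semi-axes relative to the known field
magnitude → per-axis sensitivities. Full soft-iron cross-coupling is out of
scope; degenerate orientation coverage is rejected via the design-matrix
condition number.

## Benchmarks and study conditions

`run_benchmark` generates n seeded trials per task, runs the requested
estimators on identical traces and tabulates per-trial and aggregate RMS
errors. Gyro-bias handling has three modes: *residual* (default; residual
bias drawn uniformly within ±0.02 °/s per axis, emulating already-corrected
signals), *pipeline* (an uncorrected 0.8–1.5 °/s per-axis power-up bias is
drawn, a 60 s static table acquisition is synthesized and its estimated mean
subtracted — used for the bias-correction demonstration), and *none*. The
manual task includes one 200 μT magnet event (30–35 s) by default; the
locomotion task includes the 5 μT field variation. Six trials per task at
128 samples/s are used throughout the acceptance checks — large enough for
stable means, small enough to run in about two minutes on one CPU.

Formal hypothesis testing is deliberately replaced by descriptive mean/SD
tables and seed-level paired comparisons: the corresponding human-subject
statistics answer a question about six individuals that a seeded simulation
does not reproduce.

## What passing tests do and do not show

The generators emulate the *kinematic and signal* structure of the two
tasks, not their biomechanics: no soft-tissue artifact, no impacts, no
marker-cluster processing, no sensor–reference alignment error, and the
reference orientation is exact rather than carrying the ~0.5° of a
stereophotogrammetric pipeline. Synthetic fusion errors therefore sit well
below the error levels reported for human trials, and comparisons should be
read as orderings and bounds, not as absolute accuracy predictions for real
recordings. Known limitations: heading is fundamentally unobservable from a
magnetometer alone under slow azimuthal field rotation (both filters follow
the ~5 μT path variation); the EKF's disturbance state underestimates truly
constant offsets; and the zero-order-hold integrator carries a ~0.1°
discretization error at 128 samples/s that vanishes at higher rates.
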