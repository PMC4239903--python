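"""Synthetic MIMU scenarios: rigid-body ground truth plus sensor models.

Two motor scenarios are emulated, mirroring typical human-movement trials:

* a 60 s *manual routine* (forearm-mounted unit): a sequence of smooth
  single-axis rotations of roughly 120 deg cumulative amplitude about each
  sensor axis, separated by static pauses of a couple of seconds, with a 5 s
  static prologue;
* a 180 s *locomotion* trial (trunk-mounted unit, figure-of-eight path):
  continuously alternating left/right heading turns spanning ~260 deg, small
  (<10 deg) roll/pitch gait oscillations, no static phases after the 5 s
  prologue, and vertical-axis angular velocity ~3.6x the horizontal axes.

Ground truth is generated analytically (orientation and body rates are
consistent by construction); a :class:`SensorModel` then synthesizes gyro,
accelerometer and magnetometer streams with configurable noise, bias,
inertial acceleration and magnetic disturbances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .quat import (OrientationSeries, quat_from_axis_angle, quat_multiply,
                   quat_multiply_batch, rotmat_batch)

GYRO_FULL_SCALE_DPS = 1500.0
ACCEL_FULL_SCALE_G = 6.0
MAG_FULL_SCALE_UT = 600.0

#: Homogeneous ambient field, GGF frame [uT]: 40 uT magnitude, 60 deg dip
#: (Z is positive down), representative of central-European indoor conditions.
DEFAULT_REFERENCE_FIELD = (20.0, 0.0, 34.641016151377546)


@dataclass
class SensorModel:
    """Stochastic error model of the MIMU channels (units as printed on data sheets)."""

    gyro_noise_sd: float = 2.5            # [deg/s]
    gyro_bias: tuple = (0.0, 0.0, 0.0)    # [deg/s]
    gyro_bias_walk_sd: float = 0.0        # [deg/s^2] bias rate-of-change SD
    gyro_rate_drift_frac: float = 0.01    # in-run drift SD as a fraction of mean |rate|
    gyro_drift_tau_s: float = 60.0        # correlation time of the in-run drift
    accel_noise_sd: float = 0.01          # [g]
    mag_noise_sd: float = 3.0             # [uT]
    mag_hard_iron: tuple = (0.0, 0.0, 0.0)      # [uT]
    mag_sensitivity: tuple = (1.0, 1.0, 1.0)    # [-]
    reference_field: tuple = DEFAULT_REFERENCE_FIELD  # [uT], GGF
    sample_rate: float = 128.0            # [samples/s]

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("gyro_noise_sd", "gyro_bias_walk_sd", "accel_noise_sd", "mag_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Reference orientation and the true signals used to synthesize a trace."""

    orientation: OrientationSeries            # ^GGF q_ULF
    omega_dps: np.ndarray                     # (n,3) body rates, ULF [deg/s]
    accel_inertial_g: np.ndarray              # (n,3) inertial acceleration, ULF [g]
    mag_disturbance_ggf_ut: np.ndarray        # (n,3) additive field, GGF [uT]
    static_mask: np.ndarray                   # (n,) bool
    meta: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.orientation.t

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def mag_field_ulf(self, reference_field=DEFAULT_REFERENCE_FIELD) -> np.ndarray:
        """True (undistorted-sensor) field in ULF for a given ambient field."""
        href = np.asarray(reference_field, dtype=float)
        total = href[None, :] + self.mag_disturbance_ggf_ut
        R = rotmat_batch(self.orientation.q)
        return np.einsum("nji,nj->ni", R, total)


@dataclass
class MimuTrace:
    """Uniformly sampled gyro/accel/mag streams with rate and provenance metadata."""

    gyro: np.ndarray          # (n,3) [deg/s]
    accel: np.ndarray         # (n,3) [g]
    mag: np.ndarray           # (n,3) [uT]
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        if not (len(self.gyro) == len(self.accel) == len(self.mag)):
            raise ValueError("gyro/accel/mag streams must have equal length")

    def __len__(self) -> int:
        return len(self.gyro)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate


def _minjerk(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _minjerk_rate(u: np.ndarray) -> np.ndarray:
    return 30 * u**2 - 60 * u**3 + 30 * u**4


@dataclass
class ManualRoutineParams:
    prologue_s: float = 5.0
    move_duration_s: float = 4.0
    pause_s: float = 2.5              # >= 2 s between sub-tasks
    total_rotation_deg: tuple = (108.0, 132.0)  # per-axis cumulative range
    accel_burst_g: float = 0.08       # peak inertial acceleration per sub-task
    accel_burst_hz: float = 1.5       # accelerate/decelerate cycling within a sub-task


def make_manual_routine(duration_s: float = 60.0, seed: int = 0,
                        params: ManualRoutineParams | None = None,
                        sample_rate: float = 128.0) -> GroundTruth:
    """Ground truth for the manual-routine scenario.

    Six smooth single-body-axis rotations (two per axis, opposite signs, with
    per-axis cumulative amplitude ~120 deg), each followed by a static pause,
    after a 5 s static prologue; trailing time is static.
    """
    p = params or ManualRoutineParams()
    rng = np.random.default_rng(seed)

    axes = [2, 0, 1, 0, 2, 1]
    rng.shuffle(axes)
    totals = rng.uniform(*p.total_rotation_deg, size=3)
    splits = rng.uniform(0.45, 0.6, size=3)
    amp_queue = {i: [splits[i] * totals[i], -(1 - splits[i]) * totals[i]] for i in range(3)}

    needed = p.prologue_s + len(axes) * (p.move_duration_s + p.pause_s)
    if duration_s < needed:
        raise ValueError(
            f"duration {duration_s} s too short for the static prologue and "
            f"sub-task schedule (needs >= {needed:.1f} s)")

    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    quats = np.tile([0.0, 0.0, 0.0, 1.0], (n, 1))
    omega = np.zeros((n, 3))
    accel_i = np.zeros((n, 3))
    static = np.ones(n, dtype=bool)

    q_base = np.array([0.0, 0.0, 0.0, 1.0])
    t0 = p.prologue_s
    for ax in axes:
        amp = amp_queue[ax].pop(0)
        sel = (t >= t0) & (t < t0 + p.move_duration_s)
        u = (t[sel] - t0) / p.move_duration_s
        theta = amp * _minjerk(u)
        rate = amp * _minjerk_rate(u) / p.move_duration_s
        e = np.zeros(3)
        e[ax] = 1.0
        half = 0.5 * np.radians(theta)
        dq = np.zeros((half.size, 4))
        dq[:, ax] = np.sin(half)
        dq[:, 3] = np.cos(half)
        quats[sel] = quat_multiply_batch(q_base[None, :], dq)
        omega[sel, ax] = rate
        burst_dir = rng.normal(size=3)
        burst_dir /= np.linalg.norm(burst_dir)
        # oscillatory (accelerate/decelerate) inertial burst under a smooth envelope
        profile = np.sin(np.pi * u) * np.sin(
            2 * np.pi * p.accel_burst_hz * u * p.move_duration_s)
        accel_i[sel] = p.accel_burst_g * profile[:, None] * burst_dir[None, :]
        static[sel] = False
        q_base = quat_multiply(q_base, quat_from_axis_angle(e, np.radians(amp)))
        later = t >= t0 + p.move_duration_s
        quats[later] = q_base
        t0 += p.move_duration_s + p.pause_s

    orient = OrientationSeries(t, quats, frame="ulf-in-ggf",
                               meta={"scenario": "manual", "seed": seed})
    return GroundTruth(orient, omega, accel_i, np.zeros((n, 3)), static,
                       meta={"scenario": "manual", "seed": seed,
                             "per_axis_rotation_deg": totals.tolist()})


@dataclass
class LocomotionParams:
    prologue_s: float = 5.0
    ramp_s: float = 3.0
    heading_amplitude_deg: float = 130.0   # peak-to-peak excursion 260 deg
    lap_period_range_s: tuple = (19.0, 21.0)
    step_frequency_range_hz: tuple = (0.85, 0.95)  # stride rate
    roll_amplitude_deg: float = 2.0
    pitch_amplitude_deg: float = 1.0
    heading_wobble_deg: float = 0.5
    accel_amplitude_g: tuple = (0.05, 0.03, 0.10)  # ULF x, y, z at gait frequencies
    gait_variability: float = 0.25         # step-to-step amplitude/phase modulation
    field_variation_ut: float = 5.0        # slow spatial variation along the path


def make_locomotion(duration_s: float = 180.0, seed: int = 0,
                    params: LocomotionParams | None = None,
                    sample_rate: float = 128.0) -> GroundTruth:
    """Ground truth for the figure-of-eight locomotion scenario.

    Heading follows a sinusoidal left/right alternation spanning the full
    ~260 deg excursion once per lap; roll and pitch carry small harmonic gait
    oscillations (stride and step frequency). The slowly varying ambient-field
    component seen along the path is modeled as a smooth additive GGF vector.
    """
    p = params or LocomotionParams()
    rng = np.random.default_rng(seed)
    if duration_s <= p.prologue_s + p.ramp_s:
        raise ValueError("duration too short for the static prologue and ramp-in")

    lap = rng.uniform(*p.lap_period_range_s)
    f_step = rng.uniform(*p.step_frequency_range_hz)
    ph = rng.uniform(0, 2 * np.pi, size=6)

    def ramp(tt):
        u = np.clip((tt - p.prologue_s) / p.ramp_s, 0.0, 1.0)
        return _minjerk(u)

    def yaw(tt):
        s = np.maximum(tt - p.prologue_s, 0.0)
        return ramp(tt) * (p.heading_amplitude_deg * np.sin(2 * np.pi * s / lap)
                           + p.heading_wobble_deg * np.sin(2 * np.pi * f_step * s + ph[0]))

    def pitch(tt):
        s = np.maximum(tt - p.prologue_s, 0.0)
        return ramp(tt) * p.pitch_amplitude_deg * np.sin(2 * np.pi * 2 * f_step * s + ph[1])

    def roll(tt):
        s = np.maximum(tt - p.prologue_s, 0.0)
        return ramp(tt) * p.roll_amplitude_deg * np.sin(2 * np.pi * f_step * s + ph[2])

    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    psi, th, phi = np.radians(yaw(t)), np.radians(pitch(t)), np.radians(roll(t))

    h = 1e-4  # central differences of the analytic profiles (exact to O(h^2))
    dpsi = np.radians(yaw(t + h) - yaw(t - h)) / (2 * h)
    dth = np.radians(pitch(t + h) - pitch(t - h)) / (2 * h)
    dphi = np.radians(roll(t + h) - roll(t - h)) / (2 * h)

    # z-y'-x'' Euler kinematics: body rates from Euler-angle rates
    wx = dphi - dpsi * np.sin(th)
    wy = dth * np.cos(phi) + dpsi * np.cos(th) * np.sin(phi)
    wz = dpsi * np.cos(th) * np.cos(phi) - dth * np.sin(phi)
    omega = np.degrees(np.column_stack([wx, wy, wz]))

    zeros = np.zeros(n)
    qz = np.column_stack([zeros, zeros, np.sin(psi / 2), np.cos(psi / 2)])
    qy = np.column_stack([zeros, np.sin(th / 2), zeros, np.cos(th / 2)])
    qx = np.column_stack([np.sin(phi / 2), zeros, zeros, np.cos(phi / 2)])
    quats = quat_multiply_batch(quat_multiply_batch(qz, qy), qx)

    s = np.maximum(t - p.prologue_s, 0.0)
    r = ramp(t)
    ax, ay, az = p.accel_amplitude_g
    # step-to-step gait variability: smooth random amplitude and phase
    # modulation so the inertial acceleration is not perfectly periodic
    from scipy.interpolate import CubicSpline

    def smooth_noise(scale):
        knots = np.arange(0.0, duration_s + 4.0, 4.0)
        return CubicSpline(knots, scale * rng.standard_normal(knots.size))(t)

    amp_mod = [1.0 + np.clip(smooth_noise(p.gait_variability), -0.8, 0.8)
               for _ in range(3)]
    ph_mod = [smooth_noise(2.0 * np.pi * p.gait_variability) for _ in range(3)]
    accel_i = np.column_stack([
        r * ax * amp_mod[0] * np.sin(2 * np.pi * f_step * s + ph[3] + ph_mod[0]),
        r * ay * amp_mod[1] * np.sin(2 * np.pi * f_step * s + ph[4] + ph_mod[1]),
        r * az * amp_mod[2] * np.sin(2 * np.pi * 2 * f_step * s + ph[5] + ph_mod[2]),
    ])

    amp = p.field_variation_ut / np.sqrt(3.0)
    dist = np.column_stack([
        r * amp * np.sin(2 * np.pi * s / lap + ph[0]),
        r * amp * np.sin(2 * np.pi * s / (2 * lap) + ph[1]),
        r * amp * np.sin(2 * np.pi * s / lap + ph[2]),
    ])

    static = t < p.prologue_s
    orient = OrientationSeries(t, quats, frame="ulf-in-ggf",
                               meta={"scenario": "locomotion", "seed": seed})
    return GroundTruth(orient, omega, accel_i, dist, static,
                       meta={"scenario": "locomotion", "seed": seed,
                             "lap_period_s": lap, "step_frequency_hz": f_step})


def make_static_truth(duration_s: float, sample_rate: float = 128.0,
                      seed: int = 0) -> GroundTruth:
    """Stationary ground truth (identity orientation), e.g. for calibration."""
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    orient = OrientationSeries(t, np.tile([0.0, 0.0, 0.0, 1.0], (n, 1)),
                               frame="ulf-in-ggf", meta={"scenario": "static"})
    return GroundTruth(orient, np.zeros((n, 3)), np.zeros((n, 3)),
                       np.zeros((n, 3)), np.ones(n, dtype=bool),
                       meta={"scenario": "static", "seed": seed})


#: Near-vertical default direction (GGF) of the magnet's field at the sensor:
#: passing close above a small magnet lying on the table means passing near its
#: dipole axis, where the field points along that (vertical) axis.
DEFAULT_MAGNET_DIRECTION = (0.1, 0.05, 0.99)


def add_magnet_event(truth: GroundTruth, start_s: float, duration_s: float,
                     peak_ut: float, direction=DEFAULT_MAGNET_DIRECTION) -> GroundTruth:
    """Superimpose a transient magnet-approach disturbance on the truth.

    The magnitude follows an inverse-cube dipole profile of the (smoothly
    varying) sensor-magnet distance: zero-to-peak-to-zero inside the window,
    below 1% of the peak at the window edges, untouched outside.
    """
    if peak_ut < 0:
        raise ValueError("peak must be non-negative")
    t = truth.t
    if start_s < t[0] or start_s + duration_s > t[-1]:
        raise ValueError("event window must lie inside the trace")
    events = list(truth.meta.get("magnet_events", []))
    for s0, d0 in events:
        if start_s < s0 + d0 and s0 < start_s + duration_s:
            raise ValueError("overlapping magnet events are not supported")

    dist = truth.mag_disturbance_ggf_ut.copy()
    sel = (t >= start_s) & (t <= start_s + duration_s)
    u = (t[sel] - start_s) / duration_s
    # distance ratio 8:1 between window edge and closest approach
    denom = 8.0 - 7.0 * np.sin(np.pi * u)
    profile = peak_ut / denom**3
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    dist[sel] += profile[:, None] * d[None, :]

    meta = dict(truth.meta)
    meta["magnet_events"] = events + [(start_s, duration_s)]
    return replace(truth, mag_disturbance_ggf_ut=dist, meta=meta)


def synthesize_trace(truth: GroundTruth, model: SensorModel, seed: int = 0) -> MimuTrace:
    """Corrupt ground truth with the sensor model to produce a MIMU trace.

    gyro  = omega_true + bias(t) + white noise                       [deg/s]
    accel = R(q)^T (0,0,-1) + a_inertial + white noise               [g]
    mag   = diag(s) R(q)^T (h_ref + d_GGF(t)) + hard iron + noise    [uT]
    """
    n = len(truth.omega_dps)
    if len(truth.orientation) != n:
        raise ValueError("mismatched ground-truth series lengths")
    rng = np.random.default_rng(seed)
    dt = 1.0 / model.sample_rate

    bias = np.tile(np.asarray(model.gyro_bias, dtype=float), (n, 1))
    if model.gyro_bias_walk_sd > 0:
        steps = rng.normal(0.0, model.gyro_bias_walk_sd * dt, size=(n, 3))
        bias = bias + np.cumsum(steps, axis=0)
    if model.gyro_rate_drift_frac > 0:
        # slowly varying in-run drift whose size scales with the motion
        # intensity of each axis (drift grows with angular-velocity amplitude)
        drift_sd = model.gyro_rate_drift_frac * np.mean(
            np.abs(truth.omega_dps), axis=0)
        a = np.exp(-dt / model.gyro_drift_tau_s)
        innov = rng.normal(0.0, 1.0, size=(n, 3)) * np.sqrt(1.0 - a * a)
        innov[0] = rng.normal(0.0, 1.0, size=3)  # stationary start
        drift = np.empty((n, 3))
        acc = innov[0]
        for k in range(n):
            if k:
                acc = a * acc + innov[k]
            drift[k] = acc
        bias = bias + drift * drift_sd[None, :]
    gyro = truth.omega_dps + bias + rng.normal(0.0, model.gyro_noise_sd, size=(n, 3))

    href = np.asarray(model.reference_field, dtype=float)
    sens = np.asarray(model.mag_sensitivity, dtype=float)
    iron = np.asarray(model.mag_hard_iron, dtype=float)
    gravity_dir = np.array([0.0, 0.0, -1.0])  # specific force at rest, GGF [g]

    R = rotmat_batch(truth.orientation.q)
    accel = (np.einsum("nji,j->ni", R, gravity_dir) + truth.accel_inertial_g
             + rng.normal(0.0, model.accel_noise_sd, size=(n, 3)))
    total_field = href[None, :] + truth.mag_disturbance_ggf_ut
    mag = (sens[None, :] * np.einsum("nji,nj->ni", R, total_field) + iron[None, :]
           + rng.normal(0.0, model.mag_noise_sd, size=(n, 3)))

    return MimuTrace(
        gyro=np.clip(gyro, -GYRO_FULL_SCALE_DPS, GYRO_FULL_SCALE_DPS),
        accel=np.clip(accel, -ACCEL_FULL_SCALE_G, ACCEL_FULL_SCALE_G),
        mag=np.clip(mag, -MAG_FULL_SCALE_UT, MAG_FULL_SCALE_UT),
        sample_rate=model.sample_rate,
        meta={"seed": seed, **{k: v for k, v in truth.meta.items()}},
    )


def make_static_trace(duration_s: float, model: SensorModel, seed: int = 0) -> MimuTrace:
    """Table-top static acquisition (used for gyro-bias and accel checks)."""
    truth = make_static_truth(duration_s, model.sample_rate, seed)
    return synthesize_trace(truth, model, seed)
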