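"""Quaternion extended Kalman filter (the stochastic sensor-fusion method).

State: orientation quaternion (^GGF q_ULF, scalar-last), gyro bias [rad/s] and
an ambient magnetic-disturbance vector [uT] expressed in GGF — 10 states with a
full 10x10 covariance. Prediction propagates the quaternion with bias-corrected
gyro rates through the exact constant-rate step; the bias is a random walk and
the disturbance a first-order Gauss-Markov process. Accelerometer and
magnetometer updates are applied sequentially and only after vector selection:
a measurement is used only when its magnitude (and, for the magnetometer, its
dip angle) is close enough to the expected gravitational/magnetic field, which
rejects inertial-acceleration transients and ferromagnetic disturbances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .quat import (IDENTITY, OrientationSeries, integrate_step, quat_normalize,
                   rotmat)

GRAVITY_DIR = np.array([0.0, 0.0, -1.0])  # specific force at rest, GGF [g]


@dataclass(frozen=True)
class SfParams:
    """Filter parameters in the units they are conventionally quoted in."""

    gyro_sd_dps: float = 2.5            # gyro white noise [deg/s]
    gyro_bias_walk_dps2: float = 0.0    # bias random walk [deg/s^2]
    mag_walk_ut_s: float = 1.0          # disturbance process noise [uT/s]
    mag_tau_s: float = 1.0              # disturbance correlation time [s]
    accel_meas_sd_mg: float = 10.0      # accelerometer noise [g/10^3]
    mag_meas_sd_ut: float = 3.0         # magnetometer noise [uT]
    accel_gate_mg: float = 40.0         # |  |a| - 1 g  | gate [g/10^3]
    mag_gate_ut: float = 5.0            # | |m| - |href| | gate [uT]
    dip_gate_deg: float = 15.0          # direction (dip-angle) gate


#: Task-specific presets (process/measurement statistics and gates).
MANUAL_PRESET = SfParams(gyro_sd_dps=2.5, gyro_bias_walk_dps2=0.0,
                         mag_walk_ut_s=1.0, mag_tau_s=1.0,
                         accel_meas_sd_mg=10.0, mag_meas_sd_ut=3.0,
                         accel_gate_mg=40.0, mag_gate_ut=5.0)
LOCOMOTION_PRESET = SfParams(gyro_sd_dps=2.5, gyro_bias_walk_dps2=0.01,
                             mag_walk_ut_s=10.0, mag_tau_s=1.0,
                             accel_meas_sd_mg=2.5, mag_meas_sd_ut=3.0,
                             accel_gate_mg=10.0, mag_gate_ut=5.0)
PRESETS = {"manual": MANUAL_PRESET, "locomotion": LOCOMOTION_PRESET}


@dataclass
class SfState:
    q: np.ndarray                  # (4,) unit quaternion
    gyro_bias: np.ndarray          # (3,) [rad/s]
    mag_disturbance: np.ndarray    # (3,) [uT], GGF
    P: np.ndarray                  # (10, 10)

    def copy(self) -> "SfState":
        return SfState(self.q.copy(), self.gyro_bias.copy(),
                       self.mag_disturbance.copy(), self.P.copy())


def initial_state(q0: np.ndarray = IDENTITY) -> SfState:
    P = np.zeros((10, 10))
    P[:4, :4] = 1e-4 * np.eye(4)
    P[4:7, 4:7] = np.radians(0.1) ** 2 * np.eye(3)
    P[7:, 7:] = 5.0**2 * np.eye(3)
    return SfState(quat_normalize(np.asarray(q0, dtype=float)),
                   np.zeros(3), np.zeros(3), P)


def _right_mult_matrix(p: np.ndarray) -> np.ndarray:
    """4x4 matrix M with M @ q == q (x) p."""
    u, s = p[:3], p[3]
    M = np.empty((4, 4))
    M[:3, :3] = s * np.eye(3) - _skew(u)
    M[:3, 3] = u
    M[3, :3] = -u
    M[3, 3] = s
    return M


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def _pure_quat_columns(q: np.ndarray) -> np.ndarray:
    """4x3 matrix L with columns q (x) [e_j; 0]."""
    v, w = q[:3], q[3]
    L = np.empty((4, 3))
    L[:3, :] = w * np.eye(3) + _skew(v)
    L[3, :] = -v
    return L


def _dRTu_dq(q: np.ndarray, u: np.ndarray) -> np.ndarray:
    """3x4 Jacobian of R(q)^T u with respect to the quaternion components."""
    v, w = q[:3], q[3]
    J = np.empty((3, 4))
    J[:, :3] = (-2.0 * np.outer(u, v) + 2.0 * np.outer(v, u)
                + 2.0 * (v @ u) * np.eye(3) + 2.0 * w * _skew(u))
    J[:, 3] = 2.0 * w * u - 2.0 * np.cross(v, u)
    return J


def _ensure_psd(P: np.ndarray) -> np.ndarray:
    P = 0.5 * (P + P.T)
    try:  # cheap definiteness probe; full eigen-repair only if it fails
        np.linalg.cholesky(P + 1e-12 * np.eye(len(P)))
        return P
    except np.linalg.LinAlgError:
        pass
    w, V = np.linalg.eigh(P)
    if w[0] < -1e-9:
        warnings.warn(f"covariance lost positive semi-definiteness "
                      f"(min eigenvalue {w[0]:.2e}); clipping")
    P = V @ np.diag(np.clip(w, 0.0, None)) @ V.T
    return 0.5 * (P + P.T)


def sf_predict(state: SfState, gyro_dps: np.ndarray, dt: float,
               params: SfParams) -> SfState:
    """Time update: gyro-driven quaternion propagation plus process noise."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = SfState(state.q, state.gyro_bias, state.mag_disturbance,
                    _ensure_psd(state.P))
    omega = np.radians(np.asarray(gyro_dps, dtype=float)) - state.gyro_bias
    q_new = integrate_step(state.q, omega, dt)

    angle = np.linalg.norm(omega) * dt
    if angle > 0:
        dq = np.append(omega / np.linalg.norm(omega) * np.sin(angle / 2),
                       np.cos(angle / 2))
    else:
        dq = IDENTITY
    decay = np.exp(-dt / params.mag_tau_s)

    F = np.eye(10)
    F[:4, :4] = _right_mult_matrix(dq)
    F[:4, 4:7] = -0.5 * dt * _pure_quat_columns(state.q)
    F[7:, 7:] = decay * np.eye(3)

    Q = np.zeros((10, 10))
    L = 0.5 * dt * _pure_quat_columns(state.q)
    Q[:4, :4] = np.radians(params.gyro_sd_dps) ** 2 * (L @ L.T)
    # rate-of-change convention: the bias and disturbance states may move
    # coherently at up to ~walk_sd [unit/s], i.e. a per-step SD of walk_sd*dt
    Q[4:7, 4:7] = (np.radians(params.gyro_bias_walk_dps2) * dt) ** 2 * np.eye(3)
    Q[7:, 7:] = (params.mag_walk_ut_s * dt) ** 2 * np.eye(3)

    P = F @ state.P @ F.T + Q
    return SfState(q_new, state.gyro_bias.copy(),
                   decay * state.mag_disturbance, 0.5 * (P + P.T))


def _kalman_update(state: SfState, z: np.ndarray, h: np.ndarray, H: np.ndarray,
                   meas_var: float) -> SfState:
    S = H @ state.P @ H.T + meas_var * np.eye(len(z))
    K = state.P @ H.T @ np.linalg.solve(S, np.eye(len(z)))
    dx = K @ (z - h)
    IKH = np.eye(10) - K @ H
    P = IKH @ state.P @ IKH.T + meas_var * (K @ K.T)  # Joseph form
    q = quat_normalize(state.q + dx[:4])
    return SfState(q, state.gyro_bias + dx[4:7], state.mag_disturbance + dx[7:],
                   0.5 * (P + P.T))


def _dip_deg(field: np.ndarray) -> float:
    return np.degrees(np.arctan2(field[2], np.hypot(field[0], field[1])))


def sf_update(state: SfState, accel_g: np.ndarray, mag_ut: np.ndarray,
              params: SfParams, reference_field_ut: np.ndarray) -> SfState:
    """Measurement update with vector selection (magnitude + dip-angle gates).

    A gated-out measurement leaves the state untouched, so a fully gated
    stretch degrades gracefully to pure gyro integration.
    """
    accel = np.asarray(accel_g, dtype=float)
    mag = np.asarray(mag_ut, dtype=float)
    href = np.asarray(reference_field_ut, dtype=float)
    out = state

    if abs(np.linalg.norm(accel) - 1.0) <= params.accel_gate_mg * 1e-3:
        h = rotmat(out.q).T @ GRAVITY_DIR
        H = np.zeros((3, 10))
        H[:, :4] = _dRTu_dq(out.q, GRAVITY_DIR)
        out = _kalman_update(out, accel, h, H, (params.accel_meas_sd_mg * 1e-3) ** 2)

    mag_ok = abs(np.linalg.norm(mag) - np.linalg.norm(href)) <= params.mag_gate_ut
    if mag_ok:
        mag_ggf = rotmat(out.q) @ mag
        mag_ok = abs(_dip_deg(mag_ggf) - _dip_deg(href)) <= params.dip_gate_deg
    if mag_ok:
        total = href + out.mag_disturbance
        h = rotmat(out.q).T @ total
        H = np.zeros((3, 10))
        H[:, :4] = _dRTu_dq(out.q, total)
        H[:, 7:] = rotmat(out.q).T
        out = _kalman_update(out, mag, h, H, params.mag_meas_sd_ut**2)

    if out is state:
        return state  # bit-identical prediction-only step
    out.P = _ensure_psd(out.P)
    return out


def _triad_init(accel: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Fallback orientation init from one accel/mag pair (no static prologue)."""
    d = -accel / np.linalg.norm(accel)            # gravity (down) in ULF
    e = mag - (mag @ d) * d
    e = e / np.linalg.norm(e)                     # horizontal field in ULF
    n = np.cross(e, d)
    R = np.column_stack([e, n, d])                # ULF axes of X-forward GGF
    # quaternion from rotation matrix (body-to-world R = columns of ULF in GGF)
    tr = np.trace(R)
    if tr > 0:
        w = 0.5 * np.sqrt(1 + tr)
        v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / (4 * w)
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1 + R[i, i] - R[j, j] - R[k, k])
        v = np.zeros(3)
        v[i] = 0.5 * s
        v[j] = (R[i, j] + R[j, i]) / (2 * s)
        v[k] = (R[i, k] + R[k, i]) / (2 * s)
        w = (R[k, j] - R[j, k]) / (2 * s)
    return quat_normalize(np.append(v, w))


def sf_estimator(trace, params: SfParams | str = "manual",
                 static_window_s: float = 5.0,
                 reference_field_ut: np.ndarray | None = None) -> OrientationSeries:
    """Run the EKF over a trace; returns ^GGF q_ULF per sample.

    The initial orientation is the identity (GGF is defined to coincide with
    ULF during the static prologue) and the reference magnetic field is the
    magnetometer mean over the static window. If the prologue is not static,
    falls back to a TRIAD-style init from the first accel/mag sample.
    """
    if isinstance(params, str):
        params = PRESETS[params]
    n = len(trace.gyro)
    if n == 0:
        raise ValueError("empty trace")
    dt = 1.0 / trace.sample_rate
    n_init = max(2, int(round(static_window_s * trace.sample_rate)))
    n_init = min(n_init, n)

    gyro_sd = np.asarray(trace.gyro[:n_init]).std(axis=0).max()
    if gyro_sd <= 3.0 * params.gyro_sd_dps:
        q0 = IDENTITY
        href = np.asarray(trace.mag[:n_init]).mean(axis=0)
    else:
        warnings.warn("no static prologue detected; using accel/mag TRIAD "
                      "initialization")
        q0 = _triad_init(np.asarray(trace.accel[0]), np.asarray(trace.mag[0]))
        href = rotmat(q0) @ np.asarray(trace.mag[0], dtype=float)
    if reference_field_ut is not None:
        href = np.asarray(reference_field_ut, dtype=float)

    state = initial_state(q0)
    out = np.empty((n, 4))
    out[0] = state.q
    any_update = False
    for k in range(1, n):
        state = sf_predict(state, trace.gyro[k - 1], dt, params)
        new = sf_update(state, trace.accel[k], trace.mag[k], params, href)
        any_update = any_update or new is not state
        state = new
        out[k] = state.q
    if not any_update:
        warnings.warn("all measurements gated out; estimate degrades to pure "
                      "gyro integration")
    t = np.arange(n) * dt
    return OrientationSeries(t, out, frame="ulf-in-ggf",
                             meta={"method": "sf", "reference_field": href.tolist()})
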