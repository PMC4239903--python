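"""Gradient-descent complementary filter (Madgwick-style observer).

The gyro-driven quaternion propagation is corrected, once per sample, by a
single normalized gradient-descent step on an objective that stacks the
accelerometer alignment error (rotated gravity direction vs normalized
specific force) and the magnetometer alignment error against a time-varying
reference field recomputed each step with a null Y (east) component — the
construction that confines magnetic disturbances to the heading degree of
freedom. The only tuning parameter is the gain beta [rad/s], representing the
magnitude of the gyro measurement error; no noise statistics and no
measurement gating are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ekf import GRAVITY_DIR, _dRTu_dq
from .quat import IDENTITY, OrientationSeries, integrate_step, quat_normalize, rotmat

SQRT34 = np.sqrt(3.0 / 4.0)


@dataclass(frozen=True)
class CfParams:
    beta_rad_s: float = 0.1

    def __post_init__(self) -> None:
        if self.beta_rad_s < 0:
            raise ValueError("beta must be non-negative")


def beta_from_gyro_error(omega_max_error: float) -> float:
    """Filter gain from the maximum gyro error: beta = sqrt(3/4) * omega_max.

    Unit-preserving (deg/s in, deg/s out; rad/s in, rad/s out).
    """
    if omega_max_error < 0:
        raise ValueError("maximum gyro error must be non-negative")
    return SQRT34 * omega_max_error


def beta_from_noise_sd(gyro_noise_sd: float) -> float:
    """Gain from the gyro noise SD, taking the maximum error as 3 SD."""
    return beta_from_gyro_error(3.0 * gyro_noise_sd)


def cf_step(q: np.ndarray, gyro_dps: np.ndarray, accel_g: np.ndarray,
            mag_ut: np.ndarray, dt: float, params: CfParams = CfParams()) -> np.ndarray:
    """One filter step: exact gyro propagation minus beta times the
    normalized objective gradient (single iteration), then renormalization.

    A zero-magnitude accelerometer or magnetometer sample silently drops the
    corresponding objective block for that step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    omega = np.radians(np.asarray(gyro_dps, dtype=float))
    q_pred = integrate_step(q, omega, dt)
    if params.beta_rad_s == 0.0:
        return q_pred

    grad = np.zeros(4)
    have_term = False
    accel = np.asarray(accel_g, dtype=float)
    na = np.linalg.norm(accel)
    if na > 0:
        f_g = rotmat(q).T @ GRAVITY_DIR - accel / na
        grad += _dRTu_dq(q, GRAVITY_DIR).T @ f_g
        have_term = True
    mag = np.asarray(mag_ut, dtype=float)
    nm = np.linalg.norm(mag)
    if nm > 0:
        m_hat = mag / nm
        m_ggf = rotmat(q) @ m_hat
        b_ref = np.array([np.hypot(m_ggf[0], m_ggf[1]), 0.0, m_ggf[2]])
        f_m = rotmat(q).T @ b_ref - m_hat
        grad += _dRTu_dq(q, b_ref).T @ f_m
        have_term = True

    ng = np.linalg.norm(grad)
    if not have_term or ng == 0.0:
        return q_pred
    return quat_normalize(q_pred - params.beta_rad_s * dt * grad / ng)


def cf_estimator(trace, params: CfParams = CfParams(),
                 q0: np.ndarray = IDENTITY) -> OrientationSeries:
    """Run the complementary filter over a trace; returns ^GGF q_ULF."""
    n = len(trace.gyro)
    if n == 0:
        raise ValueError("empty trace")
    dt = 1.0 / trace.sample_rate
    q = quat_normalize(np.asarray(q0, dtype=float))
    out = np.empty((n, 4))
    out[0] = q
    for k in range(1, n):
        q = cf_step(q, trace.gyro[k - 1], trace.accel[k], trace.mag[k], dt, params)
        out[k] = q
    t = np.arange(n) * dt
    return OrientationSeries(t, out, frame="ulf-in-ggf",
                             meta={"method": "cf", "beta_rad_s": params.beta_rad_s})
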