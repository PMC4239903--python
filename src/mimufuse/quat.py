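"""Quaternion algebra and strapdown integration of the kinematic equation.

Conventions (used throughout the package):

* quaternions are scalar-last, ``q = [qx, qy, qz, qw]``, Hamilton product;
* the identity (null) quaternion is ``[0, 0, 0, 1]``;
* an orientation quaternion is body-to-world: ``v_GGF = R(q) v_ULF`` where
  ULF is the sensor-fixed frame and GGF the gravity-aligned global frame
  (X forward, Y right, Z down, gravity positive down);
* angular velocity is expressed in the body frame (ULF), as measured by a
  strapdown gyroscope, and enters the kinematic differential equation
  ``dq/dt = 1/2 * Omega(omega) @ q  ==  1/2 * q (x) [omega; 0]``.

Public I/O is in degrees (and deg/s); internals work in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IDENTITY = np.array([0.0, 0.0, 0.0, 1.0])

_NORM_TOL = 1e-9


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in quaternion operation")


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0 or not np.isfinite(n):
        raise ValueError("cannot normalize zero or non-finite quaternion")
    return q / n


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a (x) b`` for scalar-last quaternions, renormalized."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a, b)
    av, aw = a[:3], a[3]
    bv, bw = b[:3], b[3]
    vec = aw * bv + bw * av + np.cross(av, bv)
    w = aw * bw - av @ bv
    return quat_normalize(np.append(vec, w))


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.concatenate([-q[:3], q[3:4]])


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` [rad] about unit ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / n
    half = 0.5 * float(angle)
    return np.append(axis * np.sin(half), np.cos(half))


def quat_to_axis_angle(q: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse of :func:`quat_from_axis_angle`; angle in [0, pi]."""
    q = quat_normalize(q)
    if q[3] < 0:  # canonical double-cover representative
        q = -q
    s = np.linalg.norm(q[:3])
    if s < 1e-12:
        return np.array([0.0, 0.0, 1.0]), 0.0
    return q[:3] / s, 2.0 * np.arctan2(s, q[3])


def rotmat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of q: ``rotmat(q) @ v == (q (x) [v;0] (x) q*).vec``."""
    x, y, z, w = quat_normalize(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    return rotmat(q) @ np.asarray(v, dtype=float)


def quat_multiply_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Hamilton product of (n, 4) arrays, renormalized."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    a, b = np.broadcast_arrays(a, b)
    av, aw = a[:, :3], a[:, 3:]
    bv, bw = b[:, :3], b[:, 3:]
    vec = aw * bv + bw * av + np.cross(av, bv)
    w = aw * bw - np.sum(av * bv, axis=1, keepdims=True)
    out = np.hstack([vec, w])
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def rotmat_batch(q: np.ndarray) -> np.ndarray:
    """(n, 3, 3) rotation matrices for an (n, 4) quaternion array."""
    q = np.asarray(q, dtype=float)
    x, y, z, w = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def omega_matrix(omega: np.ndarray) -> np.ndarray:
    """4x4 skew-symmetric matrix Omega(omega) of the kinematic equation.

    Layout ``[[-[omega x], omega], [-omega^T, 0]]`` so that
    ``0.5 * Omega(omega) @ q`` equals ``0.5 * q (x) [omega; 0]`` for body
    rates ``omega`` [rad/s].
    """
    omega = np.asarray(omega, dtype=float)
    _check_finite(omega)
    wx, wy, wz = omega
    return np.array(
        [
            [0.0, wz, -wy, wx],
            [-wz, 0.0, wx, wy],
            [wy, -wx, 0.0, wz],
            [-wx, -wy, -wz, 0.0],
        ]
    )


def integrate_step(q: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """Propagate ``q`` over ``dt`` [s] assuming constant body rate ``omega`` [rad/s].

    Exact matrix-exponential solution of the kinematic equation: a rotation of
    ``|omega| * dt`` about ``omega / |omega|`` composed on the body side.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    omega = np.asarray(omega, dtype=float)
    _check_finite(omega)
    angle = np.linalg.norm(omega) * dt
    if angle < 1e-15:
        return quat_normalize(q)
    dq = quat_from_axis_angle(omega, angle)
    return quat_multiply(q, dq)


@dataclass
class OrientationSeries:
    """Time-stamped unit-quaternion series with an explicit frame convention.

    ``frame="ulf-in-ggf"`` means each quaternion is ^GGF q_ULF (body-to-world),
    the convention every estimator in this package emits.
    """

    t: np.ndarray
    q: np.ndarray  # (n, 4) scalar-last
    frame: str = "ulf-in-ggf"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.t.size, 4):
            raise ValueError("quaternion array must be (n, 4) matching timestamps")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("orientation series contains non-unit quaternions")

    def __len__(self) -> int:
        return self.t.size

    def conjugate(self) -> "OrientationSeries":
        other = "ggf-in-ulf" if self.frame == "ulf-in-ggf" else "ulf-in-ggf"
        qc = self.q.copy()
        qc[:, :3] *= -1.0
        return OrientationSeries(self.t.copy(), qc, frame=other, meta=dict(self.meta))


def int_estimator(trace, q0: np.ndarray | None = None,
                  gyro_bias_dps: np.ndarray | None = None) -> OrientationSeries:
    """Pure strapdown (INT) estimator: numerical integration of the gyro.

    Parameters
    ----------
    trace : MimuTrace
        Measurement streams; only the gyro [deg/s] is used.
    q0 : initial orientation, default identity (GGF defined to coincide with
        ULF during the initial static posture).
    gyro_bias_dps : optional per-axis static bias [deg/s] subtracted from the
        whole angular-velocity series before integration.
    """
    gyro = np.asarray(trace.gyro, dtype=float)
    if gyro.size == 0:
        raise ValueError("empty trace")
    if gyro_bias_dps is not None:
        gyro = gyro - np.asarray(gyro_bias_dps, dtype=float)
    omega = np.radians(gyro)
    dt = 1.0 / trace.sample_rate
    q = IDENTITY.copy() if q0 is None else quat_normalize(q0)
    out = np.empty((len(gyro), 4))
    out[0] = q
    for k in range(len(gyro) - 1):
        q = integrate_step(q, omega[k], dt)
        out[k + 1] = q
    t = np.arange(len(gyro)) * dt
    return OrientationSeries(t, out, frame="ulf-in-ggf", meta={"method": "int"})


def naive_component_integration(trace) -> np.ndarray:
    """Per-axis cumulative trapezoid of the gyro signal [deg].

    The three angle series are *not* Euler angles and do not represent an
    orientation: integrating angular-velocity components separately discards
    the evolving body-to-world coupling. Provided only to demonstrate how it
    diverges from proper kinematic integration for 3-D motion.
    """
    from scipy.integrate import cumulative_trapezoid

    gyro = np.asarray(trace.gyro, dtype=float)
    dt = 1.0 / trace.sample_rate
    return cumulative_trapezoid(gyro, dx=dt, axis=0, initial=0.0)
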