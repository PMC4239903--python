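"""Signal conditioning and sensor calibration.

Covers the conditioning steps that precede orientation estimation: cubic-spline
resampling, zero-lag Butterworth low-pass filtering with Winter-style residual
analysis for cutoff selection, gyroscope static-bias estimation, a three-posture
accelerometer calibration check, and axis-aligned ellipsoid calibration of the
magnetometer (hard-iron bias + per-axis sensitivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import lstsq
from scipy.signal import butter, filtfilt

G_MPS2 = 9.81


@dataclass
class CalibrationResult:
    gyro_bias_hat_dps: np.ndarray | None = None
    accel_check_max_dev_mps2: float | None = None
    mag_bias_hat_ut: np.ndarray | None = None
    mag_sensitivity_hat: np.ndarray | None = None
    cutoff_hz: float | None = None


def resample(t: np.ndarray, x: np.ndarray, target_rate: float):
    """Cubic-spline resampling onto a uniform grid spanning the input range.

    Returns ``(t_new, x_new)``; ``x`` may be 1-D or (n, k).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 samples for cubic-spline resampling")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    spline = CubicSpline(t, x, axis=0)
    n_new = int(np.floor((t[-1] - t[0]) * target_rate)) + 1
    t_new = t[0] + np.arange(n_new) / target_rate
    return t_new, spline(t_new)


def lowpass_zero_lag(x: np.ndarray, cutoff_hz: float, sample_rate: float,
                     order: int = 2) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth low-pass filter."""
    nyq = sample_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    b, a = butter(order, cutoff_hz / nyq)
    return filtfilt(b, a, np.asarray(x, dtype=float), axis=0)


def residual_analysis_cutoff(x: np.ndarray, sample_rate: float,
                             candidates_hz: np.ndarray | None = None) -> float:
    """Winter residual analysis for low-pass cutoff selection.

    The RMS residual between the raw and filtered signal is computed for each
    candidate cutoff; a straight line is fitted to the noise-dominated upper
    half of the residual curve, and the chosen cutoff is the lowest candidate
    whose residual does not exceed that line's zero-frequency intercept (i.e.
    signal distortion balances the residual noise level).
    """
    x = np.asarray(x, dtype=float)
    if candidates_hz is None:
        candidates_hz = np.arange(1.0, min(20.0, sample_rate / 2 - 1e-9) + 1e-9, 0.5)
    candidates_hz = np.asarray(candidates_hz, dtype=float)
    resid = np.array([
        np.sqrt(np.mean((x - lowpass_zero_lag(x, fc, sample_rate)) ** 2))
        for fc in candidates_hz
    ])
    if resid.max() < 1e-3 * max(np.std(x), 1e-300):
        warnings.warn("residuals are negligible (noise-free input); returning "
                      "the upper bound of the candidate range")
        return float(candidates_hz[-1])
    tail = candidates_hz >= np.median(candidates_hz)
    slope, intercept = np.polyfit(candidates_hz[tail], resid[tail], 1)
    below = np.flatnonzero(resid <= intercept)
    if below.size == 0:
        warnings.warn("residual never drops below the noise intercept; "
                      "returning the upper bound of the candidate range")
        return float(candidates_hz[-1])
    return float(candidates_hz[below[0]])


def estimate_gyro_bias(static_trace, nominal_noise_sd_dps: float = 2.5) -> np.ndarray:
    """Per-axis mean of the gyro during a static acquisition [deg/s].

    The caller subtracts the result from the whole angular-velocity series.
    Raises if the trace does not look static (per-axis SD above 3x the nominal
    gyro noise SD indicates motion contamination).
    """
    gyro = np.asarray(static_trace.gyro, dtype=float)
    sd = gyro.std(axis=0, ddof=1)
    if np.any(sd > 3.0 * nominal_noise_sd_dps):
        raise ValueError(
            f"trace is not static (gyro SD {sd.round(2)} deg/s exceeds "
            f"3x nominal {nominal_noise_sd_dps} deg/s); bias estimate would be "
            "motion-contaminated")
    return gyro.mean(axis=0)


def accel_static_check(traces, tolerance_mps2: float = 0.02):
    """Three-posture accelerometer calibration check.

    Each trace must be a static acquisition with one ULF axis aligned with
    gravity. The per-axis mean is compared to its expected value (+-1 g on the
    aligned axis, 0 elsewhere); returns ``(max_deviation_mps2, passed)``.
    """
    if len(traces) != 3:
        raise ValueError("exactly three single-axis-aligned static traces required")
    max_dev_g = 0.0
    for trace in traces:
        mean = np.asarray(trace.accel, dtype=float).mean(axis=0)
        aligned = int(np.argmax(np.abs(mean)))
        expected = np.zeros(3)
        expected[aligned] = np.sign(mean[aligned])
        max_dev_g = max(max_dev_g, float(np.max(np.abs(mean - expected))))
    max_dev = max_dev_g * G_MPS2
    return max_dev, max_dev <= tolerance_mps2


def calibrate_magnetometer(rotation_trace, reference_magnitude_ut: float | None = None,
                           max_condition: float = 1e8):
    """Axis-aligned ellipsoid calibration of the magnetometer.

    Fits ``sum_i A_i m_i^2 + sum_i D_i m_i = 1`` by linear least squares to
    samples collected while the unit is freely rotated about its three axes,
    and extracts the hard-iron bias (ellipsoid center) and per-axis
    sensitivities (semi-axes relative to the reference field magnitude; if no
    magnitude is given, sensitivities are normalized to the mean semi-axis).

    Returns ``(bias_ut, sensitivity)``. Raises on degenerate orientation
    coverage (ill-conditioned design matrix).
    """
    mag = np.asarray(getattr(rotation_trace, "mag", rotation_trace), dtype=float)
    if mag.ndim != 2 or mag.shape[1] != 3 or len(mag) < 9:
        raise ValueError("need an (n, 3) magnetometer sample array with n >= 9")
    design = np.column_stack([mag**2, mag])
    scale = np.abs(design).mean(axis=0)
    cond = np.linalg.cond(design / scale)
    if cond > max_condition:
        raise ValueError(
            "insufficient rotation: magnetometer samples do not constrain the "
            f"ellipsoid (condition number {cond:.2e})")
    coef, *_ = lstsq(design, np.ones(len(mag)))
    A, D = coef[:3], coef[3:]
    if np.any(A <= 0):
        raise ValueError("insufficient rotation: fit is not an ellipsoid")
    bias = -D / (2.0 * A)
    gauge = 1.0 + np.sum(A * bias**2)
    semi_axes = np.sqrt(gauge / A)
    if reference_magnitude_ut is None:
        sensitivity = semi_axes / semi_axes.mean()
    else:
        sensitivity = semi_axes / reference_magnitude_ut
    return bias, sensitivity


def apply_mag_calibration(mag: np.ndarray, bias_ut: np.ndarray,
                          sensitivity: np.ndarray) -> np.ndarray:
    """Undo hard-iron bias and per-axis sensitivity: ``(m - b) / s``."""
    return (np.asarray(mag, dtype=float) - np.asarray(bias_ut)) / np.asarray(sensitivity)
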