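"""Sagittal-plane angle reconstruction and model input features.

Thigh/shank angles are measured against the horizontal line.  The sensor
frame convention is: y-axis along the body segment, x-axis perpendicular to
it in the sagittal plane, z-axis mediolateral.  At rest the accelerometer
reads the gravity reaction, so the segment angle is
``arctan(a_y / sqrt(a_x^2 + a_z^2))``; thereafter the angle is tracked by
integrating the z-axis gyroscope rate.

Feature tables follow the model feature sets used throughout the package:

``gait_inference``
    left/right thigh angle and angular speed (window length 15 frames);
``standing_up``
    EMG gradient-variability ``v5`` of both thighs (window 20);
``sitting_down``
    ``v10`` of both thighs plus the between-thigh accelerometer
    difference-variability features ``d_x`` and ``d_z`` (window 20);
``sitting_standing``
    x/z thigh accelerometer channels of both legs (window 20).

All feature columns are min-max scaled to [0, 1] with bounds fitted on
training data and reused at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_hugadb import ScaledRecording

#: Accelerometer sensitivity: counts per g at the +-2 g range.
ACC_LSB_PER_G = 16384.0
#: Gyroscope sensitivity: counts per deg/s at the +-2000 deg/s range.
GYRO_LSB_PER_DPS = 16.4

#: Counts-to-unit factors for [-1, 1]-scaled channels (scaled = counts/32768).
_SCALED_TO_G = 32768.0 / ACC_LSB_PER_G
_SCALED_TO_DPS = 32768.0 / GYRO_LSB_PER_DPS

FEATURE_KINDS = ("gait_inference", "standing_up", "sitting_down", "sitting_standing")

_KIND_COLUMNS = {
    "gait_inference": ("theta_L", "theta_R", "omega_TL", "omega_TR"),
    "standing_up": ("v5_L", "v5_R"),
    "sitting_down": ("v10_L", "v10_R", "d_x", "d_z"),
    "sitting_standing": ("T_x_L", "T_x_R", "T_z_L", "T_z_R"),
}
_KIND_WINDOW = {
    "gait_inference": 15,
    "standing_up": 20,
    "sitting_down": 20,
    "sitting_standing": 20,
}


@dataclass
class AngularSeries:
    """Thigh/shank angles (degrees) and thigh angular speeds (deg/s)."""

    theta_L: np.ndarray
    theta_R: np.ndarray
    phi_L: np.ndarray
    phi_R: np.ndarray
    omega_TL: np.ndarray
    omega_TR: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = len(self.theta_L)
        for name in ("theta_R", "phi_L", "phi_R", "omega_TL", "omega_TR"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length mismatch")
        if not all(
            np.all(np.isfinite(getattr(self, name)))
            for name in ("theta_L", "theta_R", "phi_L", "phi_R")
        ):
            raise ValueError("angles must be finite")

    def __len__(self) -> int:
        return len(self.theta_L)


@dataclass
class FeatureTable:
    """Named [0, 1]-scaled feature columns for one recognition/inference kind."""

    kind: str
    columns: pd.DataFrame
    window_length: int
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def matrix(self) -> np.ndarray:
        return self.columns.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.columns)


def moving_average(series: np.ndarray, window: int = 100) -> np.ndarray:
    """Causal trailing mean over min(window, t+1) past samples."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    csum = np.cumsum(x)
    out = np.empty_like(x)
    t = np.arange(len(x))
    head = t < window
    out[head] = csum[head] / (t[head] + 1)
    out[~head] = (csum[~head] - csum[t[~head] - window]) / window
    return out


def tilt_angle(ax, ay, az):
    """Segment angle to the horizontal, degrees in (-90, 90], from gravity.

    Invariant to positive rescaling of the acceleration vector, so any
    consistent unit (g, counts, scaled counts) may be passed.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    horiz = np.sqrt(ax**2 + az**2)
    if np.any((horiz == 0) & (ay == 0)):
        raise ValueError("zero acceleration vector: orientation undefined")
    vertical = horiz == 0
    ratio = np.divide(ay, horiz, out=np.zeros_like(horiz + ay), where=~vertical)
    angle = np.degrees(np.arctan(ratio))
    angle = np.where(vertical, 90.0 * np.sign(ay), angle)
    return angle if angle.ndim else float(angle)


def integrate_angle(theta_start: float, omega: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative rectangular integration of an angular rate, deg/s -> deg."""
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    omega = np.asarray(omega, dtype=float)
    return theta_start + np.cumsum(omega) / fs


def emg_grad_std(emg: np.ndarray, w: int) -> np.ndarray:
    """Trailing population STD of the last w+1 backward EMG differences.

    ``v_w(t) = STD{ e(t-i) - e(t-i-1) : i = 0..w }``.  Frames with an
    incomplete difference window are zero-filled.
    """
    if w < 1:
        raise ValueError(f"w must be >= 1, got {w}")
    emg = np.asarray(emg, dtype=float)
    if len(emg) <= w + 1:
        raise ValueError(f"series length {len(emg)} too short for w={w}")
    grad = np.diff(emg)  # grad[k] = e[k+1] - e[k], defined for t >= 1
    out = np.zeros(len(emg))
    win = np.lib.stride_tricks.sliding_window_view(grad, w + 1)
    out[w + 1:] = win.std(axis=1)
    return out


def paired_diff_std(left: np.ndarray, right: np.ndarray, w: int = 10) -> np.ndarray:
    """Trailing population STD of |left - right| over the last w+1 frames."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if len(left) != len(right):
        raise ValueError(f"length mismatch: {len(left)} vs {len(right)}")
    if w < 1:
        raise ValueError(f"w must be >= 1, got {w}")
    absdiff = np.abs(left - right)
    out = np.zeros(len(left))
    if len(absdiff) > w:
        win = np.lib.stride_tricks.sliding_window_view(absdiff, w + 1)
        out[w:] = win.std(axis=1)
    return out


def _require(rec: ScaledRecording, names: list[str]) -> None:
    for name in names:
        if name not in rec.channels:
            raise ValueError(f"recording lacks required channel {name!r}")


def segment_angle(
    rec: ScaledRecording,
    site: str,
    filter_window: int = 100,
    start_window: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Angle (deg) and angular speed (deg/s) of one body segment.

    The start angle comes from the gravity tilt of the moving-average
    filtered accelerometer (the wearer is assumed near-static at the start
    of a recording); the trajectory is the integral of the unfiltered
    z-gyroscope rate.  Returns ``(angle, omega)``.
    """
    acc = [f"acc_{site}_{a}" for a in "xyz"]
    gyro = f"gyro_{site}_z"
    _require(rec, acc + [gyro])
    n = len(rec)
    fax, fay, faz = (moving_average(rec.channels[c], filter_window) for c in acc)
    k = min(start_window, n) - 1
    theta0 = float(tilt_angle(fax[k], fay[k], faz[k]))
    omega = np.asarray(rec.channels[gyro], dtype=float) * _SCALED_TO_DPS
    theta = integrate_angle(theta0 - omega[0] / rec.fs, omega, rec.fs)
    return theta, omega


def compute_angular_series(rec: ScaledRecording, filter_window: int = 100) -> AngularSeries:
    """Thigh and shank angles of both legs from a scaled recording."""
    theta_L, omega_TL = segment_angle(rec, "lt", filter_window)
    theta_R, omega_TR = segment_angle(rec, "rt", filter_window)
    phi_L, _ = segment_angle(rec, "ls", filter_window)
    phi_R, _ = segment_angle(rec, "rs", filter_window)
    return AngularSeries(theta_L, theta_R, phi_L, phi_R, omega_TL, omega_TR, fs=rec.fs)


def fit_minmax_bounds(columns: pd.DataFrame) -> dict[str, tuple[float, float]]:
    return {c: (float(columns[c].min()), float(columns[c].max())) for c in columns}


def apply_minmax(columns: pd.DataFrame, bounds: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = {}
    for c in columns:
        lo, hi = bounds[c]
        if hi > lo:
            out[c] = np.clip((columns[c].to_numpy(dtype=float) - lo) / (hi - lo), 0.0, 1.0)
        else:
            # zero-range convention: constant column scales to all zeros
            out[c] = np.zeros(len(columns))
    return pd.DataFrame(out, columns=list(columns.columns))


def raw_feature_columns(rec: ScaledRecording, kind: str) -> pd.DataFrame:
    """Unscaled feature columns for ``kind`` (before [0, 1] scaling)."""
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}")
    if kind == "gait_inference":
        ang = compute_angular_series(rec)
        cols = {
            "theta_L": ang.theta_L,
            "theta_R": ang.theta_R,
            "omega_TL": ang.omega_TL,
            "omega_TR": ang.omega_TR,
        }
    elif kind == "standing_up":
        _require(rec, ["EMG_l", "EMG_r"])
        cols = {
            "v5_L": emg_grad_std(rec.channels["EMG_l"], 5),
            "v5_R": emg_grad_std(rec.channels["EMG_r"], 5),
        }
    elif kind == "sitting_down":
        _require(rec, ["EMG_l", "EMG_r", "acc_lt_x", "acc_rt_x", "acc_lt_z", "acc_rt_z"])
        cols = {
            "v10_L": emg_grad_std(rec.channels["EMG_l"], 10),
            "v10_R": emg_grad_std(rec.channels["EMG_r"], 10),
            "d_x": paired_diff_std(rec.channels["acc_lt_x"], rec.channels["acc_rt_x"], 10),
            "d_z": paired_diff_std(rec.channels["acc_lt_z"], rec.channels["acc_rt_z"], 10),
        }
    else:  # sitting_standing
        _require(rec, ["acc_lt_x", "acc_rt_x", "acc_lt_z", "acc_rt_z"])
        cols = {
            "T_x_L": np.asarray(rec.channels["acc_lt_x"], dtype=float),
            "T_x_R": np.asarray(rec.channels["acc_rt_x"], dtype=float),
            "T_z_L": np.asarray(rec.channels["acc_lt_z"], dtype=float),
            "T_z_R": np.asarray(rec.channels["acc_rt_z"], dtype=float),
        }
    return pd.DataFrame(cols, columns=list(_KIND_COLUMNS[kind]))


def build_features(
    rec: ScaledRecording,
    kind: str,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FeatureTable:
    """Assemble the feature table for ``kind``, scaled to [0, 1].

    When ``bounds`` is None the min-max bounds are fitted on this recording
    (training use) and stored on the returned table for reuse at test time.
    """
    raw = raw_feature_columns(rec, kind)
    if bounds is None:
        bounds = fit_minmax_bounds(raw)
    missing = set(raw.columns) - set(bounds)
    if missing:
        raise ValueError(f"scaling bounds missing for columns {sorted(missing)}")
    return FeatureTable(
        kind=kind,
        columns=apply_minmax(raw, bounds),
        window_length=_KIND_WINDOW[kind],
        bounds=dict(bounds),
    )
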