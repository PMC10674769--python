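"""Per-sensor calibration and filtering.

Turns the raw streams of a trial into analysis-ready signals: a
two-point calibrated, low-pass-filtered elbow angle; a band-passed EMG
plus its rectified %MVC envelope; moving-average-smoothed,
baseline-subtracted IMU channels.

All filters are zero-phase (forward-backward application) so cycle
boundaries stay aligned across sensors, and all operations preserve
series length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic_cohort import CalibrationRecord

__all__ = [
    "AngleSeries",
    "ConditionedEMG",
    "calibrate_ofs",
    "lowpass_angle",
    "compute_mvc",
    "condition_emg",
    "smooth_imu",
    "subtract_baseline",
]


@dataclass
class AngleSeries:
    """Elbow angle in degrees (0 = flexion anchor, 140 = extension anchor)."""

    angle: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("angle series contains non-finite values")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.angle)) / self.rate


@dataclass
class ConditionedEMG:
    """Band-passed EMG (for spectral features) and its %MVC envelope."""

    bandpassed: np.ndarray  # mV
    envelope_pct_mvc: np.ndarray  # %MVC, >= 0
    rate: float

    def __post_init__(self) -> None:
        if len(self.bandpassed) != len(self.envelope_pct_mvc):
            raise ValueError("bandpassed and envelope must be same length")
        if np.any(self.envelope_pct_mvc < 0):
            raise ValueError("envelope must be nonnegative")


def _odd_window_samples(window_s: float, rate: float) -> int:
    """Window length in samples, rounded to the nearest odd integer >= 1."""
    w = window_s * rate
    if w < 1.0:
        raise ValueError(
            f"window of {window_s:g} s is shorter than one sample at "
            f"{rate:g} Hz")
    n = int(round(w))
    if n % 2 == 0:  # widen to the next odd count for a centered window
        n += 1
    return max(n, 1)


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving mean with shrink-at-edges handling.

    Interior samples average the full odd-length window; near the edges
    the window shrinks to the available samples (no padding artifacts),
    so a constant input maps to itself exactly everywhere.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be a positive odd integer")
    x = np.asarray(x, dtype=float)
    kernel = np.ones(width)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def calibrate_ofs(voltage: np.ndarray, cal: CalibrationRecord,
                  rate: float) -> AngleSeries:
    """Two-point linear map from fiber voltage to elbow angle.

    The calibration anchors are the voltages recorded at the two known
    postures: 0 deg (flexion) and 140 deg (extension).
    """
    v0, v140 = cal.ofs_v_flex0, cal.ofs_v_ext140
    if v0 == v140:
        raise ValueError("OFS calibration voltages are equal; cannot map")
    angle = 140.0 * (np.asarray(voltage, dtype=float) - v0) / (v140 - v0)
    return AngleSeries(angle=angle, rate=rate)


def lowpass_angle(series: AngleSeries, fc: float = 0.5) -> AngleSeries:
    """Zero-phase 4th-order Butterworth low-pass of the angle signal."""
    if fc >= series.rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(4, fc, btype="lowpass", fs=series.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, series.angle)
    return AngleSeries(angle=filtered, rate=series.rate)


def _envelope(x: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    return moving_average(np.abs(x), _odd_window_samples(window_s, rate))


def compute_mvc(recordings, rate: float, hold_s: float = 5.0) -> float:
    """Reference MVC level from three consecutive maximal contractions.

    Each recording is rectified and smoothed with the 200 ms envelope
    window; its summary is the envelope mean over the central 3 s of the
    hold (avoiding ramp-up/release), or over the whole recording when it
    is shorter than 3 s.  The returned MVC is the mean of the three
    summaries.
    """
    if len(recordings) != 3:
        raise ValueError("MVC requires exactly 3 recordings")
    summaries = []
    for rec in recordings:
        rec = np.asarray(rec, dtype=float)
        env = _envelope(rec, rate, 0.2)
        central = int(round(3.0 * rate))
        if len(env) > central:
            lo = (len(env) - central) // 2
            env = env[lo:lo + central]
        summaries.append(float(env.mean()))
    return float(np.mean(summaries))


def condition_emg(raw: np.ndarray, mvc: float, rate: float,
                  band: tuple[float, float] = (15.0, 450.0),
                  envelope_window_s: float = 0.2) -> ConditionedEMG:
    """Band-pass, MVC-normalize, rectify and envelope the raw EMG.

    The band-passed series (4th-order Butterworth, zero phase) keeps the
    15-450 Hz myoelectric content for the spectral features; the
    envelope is the 200 ms moving mean of the rectified signal expressed
    in %MVC and carries the amplitude features.
    """
    if mvc <= 0:
        raise ValueError("MVC must be positive")
    lo, hi = band
    hi = min(hi, 0.999 * rate / 2)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    bandpassed = signal.sosfiltfilt(sos, np.asarray(raw, dtype=float))
    envelope = _envelope(bandpassed, rate, envelope_window_s) / mvc * 100.0
    return ConditionedEMG(bandpassed=bandpassed, envelope_pct_mvc=envelope,
                          rate=rate)


def smooth_imu(channels: pd.DataFrame, rate: float,
               window_ms: float = 30.0) -> pd.DataFrame:
    """Centered moving-average smoothing of every IMU channel.

    The window is rounded to the nearest odd sample count (30 ms at
    128 Hz is 3.84 samples, i.e. a 5-sample window).
    """
    width = _odd_window_samples(window_ms / 1000.0, rate)
    out = {c: moving_average(channels[c].to_numpy(), width)
           for c in channels.columns}
    return pd.DataFrame(out, index=channels.index)


def subtract_baseline(channels: pd.DataFrame, cal: CalibrationRecord,
                      sensor: str) -> pd.DataFrame:
    """Remove each channel's anatomical-position baseline offset.

    ``sensor`` selects the baseline block ("imu_wrist" or "imu_neck")
    recorded during the one-minute anatomical hold.
    """
    if sensor not in cal.imu_baseline:
        raise KeyError(f"no baseline recorded for sensor {sensor!r}")
    baseline = cal.imu_baseline[sensor]
    missing = [c for c in channels.columns if c not in baseline]
    if missing:
        raise KeyError(f"baseline missing channels: {missing}")
    return channels - pd.Series({c: baseline[c] for c in channels.columns})
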