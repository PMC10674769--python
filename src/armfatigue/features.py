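"""Per-cycle feature extraction and first-cycle normalization.

Each repetition cycle yields up to 63 features over four sensor blocks:

* IMU1 (wrist), 24: mean / std / RMS / amplitude for each of the six
  channels GyroX..AccZ;
* IMU2 (neck), 24: the same statistics;
* OFS, 8: mean, std, RMS and range of motion of the elbow angle, the
  cycle duration (t_norm), and the angle signal's mean frequency (MNF),
  median frequency (MDF) and instantaneous mean frequency (IMNF);
* EMG, 7: mean, std, RMS and amplitude of the %MVC envelope, and the
  MNF / MDF / IMNF of the band-passed signal.

Amplitude always means max minus min.  Non-frequency features are
normalized per subject by the first cycle's value (f_n = f_i / f_0),
which removes inter-subject scale; frequency features (MNF, MDF, IMNF)
are already comparable across subjects and pass through unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import signal

__all__ = [
    "SENSOR_BLOCKS",
    "IMU_STAT_ORDER",
    "OFS_FEATURES",
    "EMG_FEATURES",
    "canonical_feature_names",
    "is_frequency_feature",
    "window_stats",
    "spectral_stats",
    "imnf",
    "assemble_features",
    "normalize_features",
]

IMU_STAT_ORDER = ("mean", "std", "rms", "amp")
_IMU_CHANNEL_ORDER = ("GyroX", "GyroY", "GyroZ", "AccX", "AccY", "AccZ")

OFS_FEATURES = ("FIB_mean", "FIB_std", "FIB_RMS", "FIB_ROM",
                "FIB_tnorm", "FIB_MNF", "FIB_MDF", "FIB_IMNF")
EMG_FEATURES = ("EMG_mean", "EMG_std", "EMG_RMS", "EMG_Amp",
                "EMG_MNF", "EMG_MDF", "EMG_IMNF")

#: Canonical sensor order for the full 63-feature vector.
SENSOR_BLOCKS = ("imu1", "imu2", "ofs", "emg")

_CWT_WAVELET = "cmor1.5-1.0"
_CWT_CENTER = pywt.central_frequency(_CWT_WAVELET)


def _imu_names(prefix: str) -> list[str]:
    return [f"{prefix}_{ch}_{stat}"
            for ch in _IMU_CHANNEL_ORDER for stat in IMU_STAT_ORDER]


def canonical_feature_names(sensors=SENSOR_BLOCKS) -> list[str]:
    """Feature names in canonical order for the enabled sensor blocks.

    All four blocks give the full 63-name vector: 24 wrist-IMU, 24
    neck-IMU, 8 OFS, 7 EMG.
    """
    names: list[str] = []
    for sensor in SENSOR_BLOCKS:
        if sensor not in sensors:
            continue
        if sensor == "imu1":
            names += _imu_names("IMU1")
        elif sensor == "imu2":
            names += _imu_names("IMU2")
        elif sensor == "ofs":
            names += list(OFS_FEATURES)
        elif sensor == "emg":
            names += list(EMG_FEATURES)
    return names


def is_frequency_feature(name: str) -> bool:
    """True for spectral features (MNF / MDF / IMNF), which skip f_i/f_0."""
    return name.endswith(("MNF", "MDF", "IMNF"))


def window_stats(segment) -> tuple[float, float, float, float]:
    """(mean, sample std, RMS, max - min) of one per-cycle segment."""
    x = np.asarray(segment, dtype=float)
    if len(x) < 2:
        raise ValueError("segment must contain at least 2 samples")
    return (float(x.mean()), float(x.std(ddof=1)),
            float(np.sqrt(np.mean(x ** 2))), float(np.ptp(x)))


def spectral_stats(segment, rate: float) -> tuple[float, float]:
    """Mean and median frequency of the segment's power spectrum.

    Hann-tapered periodogram with the DC bin excluded; MNF is the
    power-weighted mean frequency and MDF the smallest frequency at
    which cumulative power reaches half the total.
    """
    x = np.asarray(segment, dtype=float)
    if len(x) < 8:
        raise ValueError("segment too short for spectral estimation")
    freqs, power = signal.periodogram(x, fs=rate, window="hann",
                                      detrend="constant")
    freqs, power = freqs[1:], power[1:]
    total = power.sum()
    if total <= 0:
        raise ValueError("zero-power segment has no defined spectrum")
    mnf = float(np.sum(freqs * power) / total)
    half_idx = np.searchsorted(np.cumsum(power), total / 2.0)
    mdf = float(freqs[min(half_idx, len(freqs) - 1)])
    return mnf, mdf


def imnf(segment, rate: float, fmin: float | None = None,
         n_freqs: int = 48) -> float:
    """Instantaneous mean frequency via the continuous wavelet transform.

    Complex-Morlet scalogram on ``n_freqs`` log-spaced frequencies in
    [fmin, rate/2]; at each instant the power-weighted mean frequency is
    formed with trapezoid weights over the log grid, and the IMNF is its
    time average over the segment.  ``fmin`` defaults to 1 Hz; pass a
    lower floor for signals whose energy lies below that (e.g. the
    elbow-angle cycle fundamental).
    """
    x = np.asarray(segment, dtype=float)
    if len(x) < 32:
        raise ValueError("segment too short for a CWT estimate")
    x = x - x.mean()
    if np.allclose(x, 0):
        raise ValueError("zero-power segment has no defined spectrum")
    if fmin is None:
        fmin = 1.0
    fmax = rate / 2.0
    if not 0 < fmin < fmax:
        raise ValueError("require 0 < fmin < rate/2")
    freqs = np.geomspace(fmin, fmax, n_freqs)
    scales = _CWT_CENTER * rate / freqs
    coef, f_out = pywt.cwt(x, scales, _CWT_WAVELET,
                           sampling_period=1.0 / rate, method="fft")
    power = np.abs(coef) ** 2
    num = np.trapezoid(power * f_out[:, None], f_out, axis=0)
    den = np.trapezoid(power, f_out, axis=0)
    valid = den > 0
    if not valid.any():
        raise ValueError("zero-power segment has no defined spectrum")
    return float(np.mean(num[valid] / den[valid]))


def assemble_features(segments: dict, rates: dict,
                      sensors=SENSOR_BLOCKS,
                      emg_imnf_fmin: float = 8.0) -> dict[str, float]:
    """Compute the named features of one cycle for the enabled sensors.

    ``segments`` holds the per-cycle slices: ``imu1`` / ``imu2``
    (DataFrames of smoothed, baseline-subtracted channels), ``angle``
    (filtered angle, deg), ``emg_bp`` and ``emg_env`` (band-passed mV
    and %MVC envelope), plus ``duration`` in seconds.  EMG amplitude
    features come from the envelope and EMG spectral features from the
    band-passed signal; the angle's IMNF floor adapts to the cycle
    fundamental (one cycle per window).
    """
    out: dict[str, float] = {}
    for sensor in SENSOR_BLOCKS:
        if sensor not in sensors:
            continue
        if sensor in ("imu1", "imu2"):
            if sensor not in segments:
                raise KeyError(f"enabled sensor {sensor!r} has no segment")
            prefix = "IMU1" if sensor == "imu1" else "IMU2"
            channels = segments[sensor]
            for ch in _IMU_CHANNEL_ORDER:
                mean, std, rms, amp = window_stats(channels[ch])
                out[f"{prefix}_{ch}_mean"] = mean
                out[f"{prefix}_{ch}_std"] = std
                out[f"{prefix}_{ch}_rms"] = rms
                out[f"{prefix}_{ch}_amp"] = amp
        elif sensor == "ofs":
            if "angle" not in segments:
                raise KeyError("enabled sensor 'ofs' has no angle segment")
            angle = np.asarray(segments["angle"], dtype=float)
            duration = float(segments["duration"])
            mean, std, rms, rom = window_stats(angle)
            mnf, mdf = spectral_stats(angle, rates["angle"])
            out.update({
                "FIB_mean": mean, "FIB_std": std, "FIB_RMS": rms,
                "FIB_ROM": rom, "FIB_tnorm": duration,
                "FIB_MNF": mnf, "FIB_MDF": mdf,
                "FIB_IMNF": imnf(angle, rates["angle"],
                                 fmin=1.0 / duration),
            })
        elif sensor == "emg":
            if "emg_bp" not in segments or "emg_env" not in segments:
                raise KeyError("enabled sensor 'emg' has no segments")
            env = np.asarray(segments["emg_env"], dtype=float)
            bp = np.asarray(segments["emg_bp"], dtype=float)
            mean, std, rms, amp = window_stats(env)
            mnf, mdf = spectral_stats(bp, rates["emg"])
            out.update({
                "EMG_mean": mean, "EMG_std": std, "EMG_RMS": rms,
                "EMG_Amp": amp, "EMG_MNF": mnf, "EMG_MDF": mdf,
                "EMG_IMNF": imnf(bp, rates["emg"], fmin=emg_imnf_fmin),
            })
    return out


def normalize_features(table: pd.DataFrame,
                       feature_cols=None) -> pd.DataFrame:
    """First-cycle normalization f_n = f_i / f_0, per subject.

    Every non-frequency feature column is divided by that subject's
    first-cycle value (ordering by the ``cycle`` column); frequency
    features pass through.  A zero first-cycle value is refused by name
    rather than silently padded.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c in set(canonical_feature_names())]
    norm_cols = [c for c in feature_cols if not is_frequency_feature(c)]
    out = table.sort_values(["subject_id", "cycle"]).copy()
    out[norm_cols] = out[norm_cols].astype(float)
    firsts = out.groupby("subject_id")[norm_cols].transform("first")
    zero_mask = (firsts == 0).any(axis=0)
    if zero_mask.any():
        bad = firsts.columns[zero_mask].tolist()
        subjects = out.loc[(firsts[bad] == 0).any(axis=1),
                           "subject_id"].unique().tolist()
        raise ValueError(
            f"first-cycle value is zero for feature(s) {bad} "
            f"(subject(s) {subjects}); cannot normalize")
    out[norm_cols] = out[norm_cols].to_numpy() / firsts.to_numpy()
    return out
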