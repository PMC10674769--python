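"""Synthetic multi-sensor biceps-curl fatigue cohort.

Emulates a repetitive dumbbell-curl session instrumented with an
optical-fiber elbow-angle sensor (OFS), a biceps surface-EMG channel,
and two 6-channel IMUs (wrist and neck), with a Borg CR10 perceived
exertion rating queried at a fixed interval until the subject reports 10
and the trial stops.

Everything is driven by a latent fatigue variable ``u(t) = borg(t)/10``
that rises monotonically from 0 to 1 over the trial:

* the EMG envelope amplitude grows and its spectral content compresses
  toward lower frequencies (the canonical surface-EMG fatigue signature);
* elbow flexion-extension cycles lengthen and their range of motion
  shrinks;
* the neck IMU picks up growing compensatory oscillation;
* the wrist IMU follows the angle kinematics (angular velocity and
  linear acceleration of the forearm) and therefore slows with fatigue.

All randomness flows from explicit integer seeds; identical seeds give
bitwise-identical trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy import signal

__all__ = [
    "IMU_CHANNELS",
    "CR10_GRID",
    "NoiseLevels",
    "SyntheticParams",
    "CalibrationRecord",
    "SensorTrial",
    "borg_trajectory",
    "generate_trial",
    "generate_cohort",
]

IMU_CHANNELS = ("GyroX", "GyroY", "GyroZ", "AccX", "AccY", "AccZ")

#: CR10 response grid: integers 0..10 plus the 0.5 step between 0 and 1.
CR10_GRID = np.array([0.0, 0.5] + [float(k) for k in range(1, 11)])

# Latent Borg ramp: monotone PCHIP through milestones placed so that the
# time spent below 3 / between 3 and 6 / above 6 roughly reproduces the
# observed state proportions (~37/28/36 %), with the characteristic slow
# plateau at 9 before the terminal 10.
_BORG_KNOTS_X = np.array([0.0, 0.37, 0.65, 0.85, 1.0])
_BORG_KNOTS_Y = np.array([0.0, 3.0, 6.0, 9.0, 10.0])
_BORG_RAMP = PchipInterpolator(_BORG_KNOTS_X, _BORG_KNOTS_Y)

_GRAVITY = 9.81  # m/s^2
_FOREARM_RADIUS = 0.30  # m, wrist sensor lever arm about the elbow


@dataclass(frozen=True)
class NoiseLevels:
    """Additive white-noise standard deviations, in each stream's units."""

    ofs_v: float = 0.005  # V on the raw fiber voltage
    emg_mv: float = 0.002  # mV broadband sensor floor (a few microvolts)
    imu_gyro: float = 1.0  # deg/s
    imu_acc: float = 0.05  # m/s^2


@dataclass
class SyntheticParams:
    """Cohort-level generator settings.

    Rates and slopes are expressed "per unit fatigue": the change between
    a fresh subject (u = 0) and one at the Borg-10 stop point (u = 1).
    """

    n_subjects: int = 30
    trial_duration_max: float = 600.0  # s, safety cap
    time_to_fatigue: float = 150.0  # s for the latent ramp to reach Borg 10
    base_cycle_period: float = 3.0  # s per curl repetition when fresh
    cycle_slowing_rate: float = 0.5  # fractional period growth at u = 1
    rom_initial: float = 120.0  # deg of elbow excursion when fresh
    rom_decay: float = 30.0  # deg lost at u = 1
    emg_amp_initial: float = 3.0  # %MVC envelope when fresh
    emg_amp_slope: float = 6.0  # %MVC gained at u = 1
    emg_center_freq_initial: float = 90.0  # Hz spectral centroid when fresh
    emg_freq_compression: float = 25.0  # Hz lost at u = 1
    emg_half_bandwidth: float = 35.0  # Hz, half-width of the EMG band
    neck_compensation_gain: float = 1.0  # scales neck oscillation growth
    noise_sd: NoiseLevels = field(default_factory=NoiseLevels)
    borg_query_interval: float = 20.0  # s between CR10 queries
    fs_ofs: float = 100.0  # Hz (not stated by the protocol; configurable)
    fs_emg: float = 1024.0  # Hz
    fs_imu: float = 128.0  # Hz
    subject_sigma: float = 0.08  # log-normal inter-subject spread
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "trial_duration_max", "time_to_fatigue", "base_cycle_period",
            "rom_initial", "emg_amp_initial", "emg_center_freq_initial",
            "emg_half_bandwidth", "borg_query_interval",
            "fs_ofs", "fs_emg", "fs_imu",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("cycle_slowing_rate", "rom_decay", "emg_amp_slope",
                     "emg_freq_compression", "neck_compensation_gain",
                     "subject_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.emg_center_freq_initial >= self.fs_emg / 2:
            raise ValueError("emg_center_freq_initial must be below fs_emg/2")


@dataclass
class CalibrationRecord:
    """Per-subject calibration: MVC level, OFS anchors, IMU baselines."""

    mvc_value: float  # mV, envelope scale
    ofs_v_flex0: float  # V at 0 deg (full flexion reference)
    ofs_v_ext140: float  # V at 140 deg (extension reference)
    imu_baseline: dict[str, dict[str, float]]  # sensor -> channel -> mean

    def __post_init__(self) -> None:
        if self.mvc_value <= 0:
            raise ValueError("mvc_value must be positive")
        if self.ofs_v_flex0 == self.ofs_v_ext140:
            raise ValueError("OFS calibration voltages must differ")


@dataclass
class SensorTrial:
    """One subject's raw multi-rate streams plus Borg events and metadata."""

    subject_id: str
    duration: float  # s, time of the trial-ending Borg event
    fs_ofs: float
    fs_emg: float
    fs_imu: float
    ofs_voltage: np.ndarray  # V
    emg: np.ndarray  # mV
    imu_wrist: pd.DataFrame  # columns IMU_CHANNELS
    imu_neck: pd.DataFrame
    borg_events: list[tuple[float, float]]  # (time s, CR10 rating)
    calibration: CalibrationRecord
    load_kg: float

    def times(self, stream: str) -> np.ndarray:
        fs = {"ofs": self.fs_ofs, "emg": self.fs_emg,
              "imu": self.fs_imu}[stream]
        n = {"ofs": len(self.ofs_voltage), "emg": len(self.emg),
             "imu": len(self.imu_wrist)}[stream]
        return np.arange(n) / fs


@dataclass
class _SubjectProfile:
    """Per-subject perturbation of the cohort parameters."""

    time_to_fatigue: float
    base_cycle_period: float
    rom_initial: float
    rom_decay: float
    emg_amp_initial: float
    emg_amp_slope: float
    emg_center_freq: float
    emg_freq_compression: float
    neck_gain: float
    mvc_value: float
    load_kg: float


def _subject_profile(params: SyntheticParams,
                     rng: np.random.Generator) -> _SubjectProfile:
    def jitter() -> float:
        return float(np.exp(rng.normal(0.0, params.subject_sigma)))

    return _SubjectProfile(
        time_to_fatigue=params.time_to_fatigue * jitter(),
        base_cycle_period=params.base_cycle_period * jitter(),
        rom_initial=min(params.rom_initial * jitter(), 138.0),
        rom_decay=params.rom_decay * jitter(),
        emg_amp_initial=params.emg_amp_initial * jitter(),
        emg_amp_slope=params.emg_amp_slope * jitter(),
        emg_center_freq=params.emg_center_freq_initial * jitter(),
        emg_freq_compression=params.emg_freq_compression * jitter(),
        neck_gain=params.neck_compensation_gain * jitter(),
        mvc_value=1.0 * jitter(),
        load_kg=float(rng.choice([2.5, 4.5])),
    )


def _latent_borg(t: np.ndarray | float, time_to_fatigue: float) -> np.ndarray:
    x = np.clip(np.asarray(t, dtype=float) / time_to_fatigue, 0.0, 1.0)
    return np.asarray(_BORG_RAMP(x))


def _floor_to_grid(values: np.ndarray) -> np.ndarray:
    """Largest CR10 grid value <= each latent value (monotone by design)."""
    idx = np.searchsorted(CR10_GRID, np.asarray(values) + 1e-12,
                          side="right") - 1
    return CR10_GRID[np.clip(idx, 0, len(CR10_GRID) - 1)]


def borg_trajectory(t, params: SyntheticParams,
                    rng: np.random.Generator | None = None):
    """CR10 rating(s) at time(s) ``t`` for one subject.

    The latent ramp rises monotonically from 0 at t = 0 to 10 at the
    subject's time-to-fatigue and is floored onto the CR10 response grid,
    so the reported rating starts at 0, is nondecreasing, plateaus at 9
    and reaches 10 exactly when the latent ramp does.  ``rng``, when
    given, supplies the subject's time-to-fatigue jitter (first draw);
    pass the same generator state to reproduce a subject.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    ttf = params.time_to_fatigue
    if rng is not None:
        ttf *= float(np.exp(rng.normal(0.0, params.subject_sigma)))
    out = _floor_to_grid(_latent_borg(t_arr, ttf))
    return float(out) if np.isscalar(t) else out


def _borg_schedule(profile: _SubjectProfile,
                   params: SyntheticParams) -> list[tuple[float, float]]:
    """Query every ``borg_query_interval`` seconds until the first 10."""
    events: list[tuple[float, float]] = []
    k = 0
    while True:
        t = k * params.borg_query_interval
        rating = float(_floor_to_grid(_latent_borg(t, profile.time_to_fatigue)))
        events.append((t, rating))
        if rating >= 10.0 or t >= params.trial_duration_max:
            break
        k += 1
    return events


def _cycle_phase(t: np.ndarray, u: np.ndarray,
                 profile: _SubjectProfile, params: SyntheticParams
                 ) -> np.ndarray:
    """Integrated phase of the curl cycle; the period grows with fatigue."""
    period = profile.base_cycle_period * (1.0 + params.cycle_slowing_rate * u)
    dphi = 2.0 * np.pi / period
    dt = np.gradient(t) if len(t) > 1 else np.array([0.0])
    return np.cumsum(dphi * dt)


def _shaped_emg_noise(n: int, fs: float, fc: np.ndarray,
                      half_bw: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise whose band center follows fc(t).

    Overlap-add of 2 s Hann-windowed blocks of band-passed white noise
    (50% hop satisfies constant overlap-add), each block filtered around
    the local center frequency.
    """
    block = int(round(2.0 * fs))
    block += block % 2  # even, for the half-block hop
    hop = block // 2
    window = np.hanning(block)
    # Pad one hop on each side so the interior sees full Hann overlap
    # (sum of 50%-overlapped Hann windows is ~1) from sample 0 onward.
    out = np.zeros(n + 2 * block)
    nyq = fs / 2.0
    for start in range(0, n + block, hop):
        center = fc[np.clip(start - hop + block // 2, 0, n - 1)]
        lo = max(center - half_bw, 1.0)
        hi = min(center + half_bw, 0.98 * nyq)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs,
                            output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(block))
        sd = x.std()
        if sd > 0:
            x /= sd
        out[start:start + block] += window * x
    return out[hop:hop + n]


def generate_trial(params: SyntheticParams, subject_id: str,
                   seed: int) -> SensorTrial:
    """Generate one subject's full raw trial.

    The trial runs until the first Borg query answered with 10 (capped at
    ``trial_duration_max``); all streams share time origin 0 and span the
    trial duration at their native rates.
    """
    rng = np.random.default_rng(seed)
    profile = _subject_profile(params, rng)
    events = _borg_schedule(profile, params)
    duration = events[-1][0]
    noise = params.noise_sd

    def grid(fs: float) -> np.ndarray:
        return np.arange(int(round(duration * fs)) + 1) / fs

    # --- kinematics on the EMG grid (finest), interpolated elsewhere ---
    t_emg = grid(params.fs_emg)
    u_emg = _latent_borg(t_emg, profile.time_to_fatigue) / 10.0
    phase = _cycle_phase(t_emg, u_emg, profile, params)

    rom = np.clip(profile.rom_initial - profile.rom_decay * u_emg, 5.0, 138.0)
    angle_emg = 70.0 - (rom / 2.0) * np.cos(phase)  # deg, in (0, 140)

    # --- OFS voltage: inverse of the two-point angle calibration ---
    v_flex0 = 2.0 + rng.normal(0.0, 0.02)
    v_ext140 = 1.0 + rng.normal(0.0, 0.02)
    t_ofs = grid(params.fs_ofs)
    angle_ofs = np.interp(t_ofs, t_emg, angle_emg)
    ofs_voltage = (v_flex0 + (angle_ofs / 140.0) * (v_ext140 - v_flex0)
                   + rng.normal(0.0, noise.ofs_v, len(t_ofs)))

    # --- EMG: band-shaped noise, envelope amplitude tracks fatigue ------
    fc = np.clip(profile.emg_center_freq
                 - profile.emg_freq_compression * u_emg,
                 params.emg_half_bandwidth + 16.0, 449.0)
    carrier = _shaped_emg_noise(len(t_emg), params.fs_emg, fc,
                                params.emg_half_bandwidth, rng)
    burst = 0.25 + 0.75 * ((1.0 - np.cos(phase)) / 2.0) ** 1.5
    target_pct = (profile.emg_amp_initial
                  + profile.emg_amp_slope * u_emg) * burst
    sigma = (target_pct / 100.0) * profile.mvc_value / np.sqrt(2.0 / np.pi)
    emg = sigma * carrier + rng.normal(0.0, noise.emg_mv, len(t_emg))

    # --- IMUs ----------------------------------------------------------
    t_imu = grid(params.fs_imu)
    u_imu = _latent_borg(t_imu, profile.time_to_fatigue) / 10.0
    angle_imu = np.interp(t_imu, t_emg, angle_emg)
    phase_imu = np.interp(t_imu, t_emg, phase)
    angle_rad = np.deg2rad(angle_imu)
    omega = np.gradient(angle_imu, t_imu)  # deg/s
    alpha = np.gradient(np.deg2rad(omega), t_imu)  # rad/s^2
    lin_acc = _FOREARM_RADIUS * alpha  # tangential, m/s^2

    baselines = {
        "imu_wrist": {ch: float(rng.normal(0.0, 0.1)) for ch in IMU_CHANNELS},
        "imu_neck": {ch: float(rng.normal(0.0, 0.1)) for ch in IMU_CHANNELS},
    }
    baselines["imu_wrist"]["AccZ"] += _GRAVITY
    baselines["imu_neck"]["AccZ"] += _GRAVITY

    def gyro_noise(size: int) -> np.ndarray:
        return rng.normal(0.0, noise.imu_gyro, size)

    def acc_noise(size: int) -> np.ndarray:
        return rng.normal(0.0, noise.imu_acc, size)

    nw = len(t_imu)
    wrist = {
        "GyroX": omega + gyro_noise(nw),
        "GyroY": 0.3 * omega + gyro_noise(nw),
        "GyroZ": 0.15 * omega + gyro_noise(nw),
        "AccX": lin_acc + acc_noise(nw),
        "AccY": _GRAVITY * np.cos(angle_rad) * 0.6 + 0.3 * lin_acc
                + acc_noise(nw),
        "AccZ": _GRAVITY * np.sin(angle_rad) * 0.3 + acc_noise(nw),
    }
    # Neck compensation: oscillation locked to the curl cycle whose
    # amplitude grows with fatigue (lateral/forward neck flexion).
    neck_gyro_amp = 8.0 * profile.neck_gain * u_imu
    neck_acc_amp = 0.6 * profile.neck_gain * u_imu
    neck = {
        "GyroX": neck_gyro_amp * np.sin(phase_imu) + gyro_noise(nw),
        "GyroY": 0.6 * neck_gyro_amp * np.sin(phase_imu + 0.7)
                 + gyro_noise(nw),
        "GyroZ": 0.3 * neck_gyro_amp * np.sin(phase_imu + 1.3)
                 + gyro_noise(nw),
        "AccX": neck_acc_amp * np.sin(phase_imu + 0.4) + acc_noise(nw),
        "AccY": 0.7 * neck_acc_amp * np.sin(phase_imu + 1.1) + acc_noise(nw),
        "AccZ": 0.4 * neck_acc_amp * np.sin(phase_imu + 1.9) + acc_noise(nw),
    }
    imu_wrist = pd.DataFrame(
        {ch: wrist[ch] + baselines["imu_wrist"][ch] for ch in IMU_CHANNELS})
    imu_neck = pd.DataFrame(
        {ch: neck[ch] + baselines["imu_neck"][ch] for ch in IMU_CHANNELS})

    calibration = CalibrationRecord(
        mvc_value=profile.mvc_value,
        ofs_v_flex0=v_flex0,
        ofs_v_ext140=v_ext140,
        imu_baseline=baselines,
    )
    return SensorTrial(
        subject_id=subject_id,
        duration=duration,
        fs_ofs=params.fs_ofs,
        fs_emg=params.fs_emg,
        fs_imu=params.fs_imu,
        ofs_voltage=ofs_voltage,
        emg=emg,
        imu_wrist=imu_wrist,
        imu_neck=imu_neck,
        borg_events=events,
        calibration=calibration,
        load_kg=profile.load_kg,
    )


def generate_cohort(params: SyntheticParams, seed: int | None = None
                    ) -> tuple[list[SensorTrial], dict]:
    """Generate ``n_subjects`` trials plus a reproducibility manifest.

    Per-trial seeds are derived from the cohort seed via
    ``numpy.random.SeedSequence`` so subjects are independent and the
    whole cohort is reproducible from a single integer.
    """
    if params.n_subjects < 2:
        raise ValueError("need at least 2 subjects to form a cohort")
    cohort_seed = params.seed if seed is None else int(seed)
    ss = np.random.SeedSequence(cohort_seed)
    trial_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(
        params.n_subjects, dtype=np.uint32)]
    trials = []
    manifest_trials = []
    for i, trial_seed in enumerate(trial_seeds):
        subject_id = f"S{i + 1:02d}"
        trial = generate_trial(params, subject_id, trial_seed)
        trials.append(trial)
        manifest_trials.append({
            "subject_id": subject_id,
            "seed": trial_seed,
            "duration_s": trial.duration,
            "n_borg_events": len(trial.borg_events),
            "load_kg": trial.load_kg,
        })
    params_dict = asdict(params)
    params_dict["noise_sd"] = asdict(params.noise_sd)
    manifest = {
        "cohort_seed": cohort_seed,
        "params": params_dict,
        "trials": manifest_trials,
    }
    return trials, manifest
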