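"""Repetition-cycle detection and fatigue-state labeling.

A repetition cycle is the peak-to-peak interval of the filtered elbow
angle: successive maxima of the flexion-extension trace delimit one
biceps curl.  Borg CR10 ratings, queried sparsely during the trial, are
linearly interpolated over time; each cycle takes the interpolated
rating at its midpoint and is mapped to one of three ordinal fatigue
states (LF / MOF / HF) by configurable Borg cut-points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .signal_conditioning import AngleSeries

__all__ = [
    "STATES",
    "CycleWindow",
    "StateBoundaries",
    "interpolate_borg",
    "detect_cycles",
    "assign_state",
    "label_cycles",
    "slice_streams",
]

STATES = ("LF", "MOF", "HF")


@dataclass
class CycleWindow:
    """One repetition interval, optionally labeled with a Borg state."""

    index: int
    t_start: float
    t_end: float
    borg: float | None = None
    state: str | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass(frozen=True)
class StateBoundaries:
    """Borg cut-points: LF = [0, lf_max], MOF = (lf_max, mof_max], HF above.

    The defaults (3 and 6) follow the CR10 verbal anchors ("moderate"
    around 3, "very strong" around 7); they are configuration, not a
    measured quantity.
    """

    lf_max: float = 3.0
    mof_max: float = 6.0

    def __post_init__(self) -> None:
        if not (0 <= self.lf_max < self.mof_max < 10):
            raise ValueError("require 0 <= lf_max < mof_max < 10")


def interpolate_borg(events, query_times) -> np.ndarray:
    """Piecewise-linear Borg rating at arbitrary times.

    Before the first event the first rating holds; after the last event
    the last rating holds (the subject's final report).
    """
    if len(events) == 0:
        raise ValueError("no Borg events to interpolate")
    times = np.asarray([e[0] for e in events], dtype=float)
    ratings = np.asarray([e[1] for e in events], dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("Borg event times must be strictly increasing")
    return np.interp(np.asarray(query_times, dtype=float), times, ratings)


def _estimate_period(angle: np.ndarray, rate: float) -> float | None:
    """Dominant cycle period from the autocorrelation's first peak."""
    x = angle - angle.mean()
    if np.allclose(x, 0):
        return None
    n = len(x)
    acf = signal.fftconvolve(x, x[::-1], mode="full")[n - 1:]
    acf /= acf[0]
    peaks, _ = signal.find_peaks(acf)
    if len(peaks) == 0:
        return None
    return peaks[0] / rate


def detect_cycles(series: AngleSeries) -> list[CycleWindow]:
    """Detect repetition cycles as peak-to-peak windows of the angle.

    Peak picking is scale-free: the minimum peak separation is half the
    autocorrelation-estimated cycle period and the minimum prominence is
    20% of the signal range, which tolerates both the cycle slowing and
    the range-of-motion decay that fatigue induces.  ``n`` peaks yield
    ``n - 1`` non-overlapping windows; fewer than two peaks yield an
    empty list with a warning.
    """
    angle = series.angle
    span = float(np.ptp(angle))
    period = _estimate_period(angle, series.rate)
    if span <= 0 or period is None:
        warnings.warn("no cycles detected in angle signal")
        return []
    distance = max(int(round(0.5 * period * series.rate)), 1)
    peaks, _ = signal.find_peaks(angle, distance=distance,
                                 prominence=0.2 * span)
    if len(peaks) < 2:
        warnings.warn("fewer than two angle peaks; no cycles detected")
        return []
    t = peaks / series.rate
    return [CycleWindow(index=i, t_start=float(t[i]), t_end=float(t[i + 1]))
            for i in range(len(peaks) - 1)]


def assign_state(borg: float, bounds: StateBoundaries = StateBoundaries()
                 ) -> str:
    """Map a Borg rating to its fatigue state; states partition [0, 10]."""
    if not (0 <= borg <= 10):
        raise ValueError(f"Borg rating {borg} outside [0, 10]")
    if borg <= bounds.lf_max:
        return "LF"
    if borg <= bounds.mof_max:
        return "MOF"
    return "HF"


def label_cycles(windows: list[CycleWindow], events,
                 bounds: StateBoundaries = StateBoundaries()
                 ) -> list[CycleWindow]:
    """Attach the midpoint-interpolated Borg rating and state to windows."""
    if not windows:
        return []
    mids = [w.midpoint for w in windows]
    borg = interpolate_borg(events, mids)
    return [
        CycleWindow(index=w.index, t_start=w.t_start, t_end=w.t_end,
                    borg=float(b), state=assign_state(float(b), bounds))
        for w, b in zip(windows, borg)
    ]


def slice_streams(streams: dict, rates: dict,
                  windows: list[CycleWindow]) -> list[dict]:
    """Cut every stream into per-cycle segments at its native rate.

    ``streams`` maps names to 1-D arrays or DataFrames sharing time
    origin 0; ``rates`` maps the same names to sampling rates in Hz.
    Windows are half-open ``[t_start, t_end)`` so consecutive cycles
    share no samples.  A window extending past the end of any recording
    raises.
    """
    out = []
    for w in windows:
        segs = {}
        for name, data in streams.items():
            fs = rates[name]
            i0 = int(np.ceil(w.t_start * fs - 1e-9))
            i1 = int(np.ceil(w.t_end * fs - 1e-9))
            if i1 > len(data):
                raise ValueError(
                    f"window [{w.t_start}, {w.t_end}) s exceeds stream "
                    f"{name!r} of {len(data) / fs:.2f} s")
            segs[name] = data[i0:i1] if not hasattr(data, "iloc") \
                else data.iloc[i0:i1]
        segs["window"] = w
        out.append(segs)
    return out
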