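"""Burst-level signal computations.

Heart-rate tags record short ECG bursts (7.5 s at 200 Hz every 10 min)
and longer tri-axial acceleration bursts (60 s at 25 Hz).  This module
computes heart rate from R-peaks detected in an ECG burst, the
theoretical floor on heart rate measurable in a finite window, and the
external-acceleration activity metric (vector-norm acceleration above
standard gravity, in milli-g, akin to VeDBA/MSA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ECGTrace",
    "AccelBurst",
    "PeakSet",
    "NoSignalError",
    "InsufficientPeaksError",
    "detect_r_peaks",
    "hr_from_peaks",
    "theoretical_min_hr",
    "external_acceleration",
    "round_half_up",
]


class NoSignalError(ValueError):
    """The trace carries no signal (e.g. flat line)."""


class InsufficientPeaksError(ValueError):
    """Too few R-peaks to compute a heart rate."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (tag convention)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ECGTrace:
    """A single ECG burst: dimensionless samples at a fixed rate."""

    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


@dataclass(frozen=True)
class AccelBurst:
    """A tri-axial acceleration burst in milli-g, gravity included."""

    sample_rate: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ax", "ay", "az"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).ravel()
            )
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("acceleration axes must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate


@dataclass(frozen=True)
class PeakSet:
    """Detected R-peak sample indices (strictly increasing)."""

    indices: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).ravel()
        if len(idx) > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.sample_rate

    @property
    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.times_s)


def detect_r_peaks(
    trace: ECGTrace, min_rr_s: float = 0.45, threshold_frac: float = 0.6
) -> PeakSet:
    """Detect R-peaks as local maxima above a fraction of the trace maximum.

    Peaks must exceed ``threshold_frac * max(samples)`` and be separated
    by at least ``min_rr_s`` seconds (default 0.45 s, a ~133 bpm ceiling
    just above the 120 bpm quality-control bound).  Deterministic.
    """
    x = trace.samples
    if len(x) == 0:
        raise NoSignalError("empty trace")
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie strictly between 0 and 1")
    if float(x.max()) == float(x.min()):
        raise NoSignalError("flat trace: no ECG signal present")
    height = threshold_frac * float(x.max())
    distance = max(1, int(round(min_rr_s * trace.sample_rate)))
    idx, _ = find_peaks(x, height=height, distance=distance)
    return PeakSet(indices=idx, sample_rate=trace.sample_rate)


def hr_from_peaks(peaks: PeakSet) -> int:
    """Heart rate in integer bpm from the mean R-R interval.

    HR = 60 / mean(R-R seconds), rounded half-up — matching the tag's
    integer bpm output.  Requires at least two peaks.
    """
    if len(peaks) < 2:
        raise InsufficientPeaksError(
            f"need >= 2 R-peaks to compute heart rate, got {len(peaks)}"
        )
    mean_rr = float(np.mean(peaks.rr_intervals_s))
    return round_half_up(60.0 / mean_rr)


class MinHR(NamedTuple):
    bpm: float
    bpm_int: int


def theoretical_min_hr(window_s: float) -> MinHR:
    """Lowest heart rate measurable in a window of ``window_s`` seconds.

    A rate is measurable only if one full inter-beat interval fits the
    window, so the floor is 60 / window_s bpm.  Returns the exact value
    and its rounded-up integer companion (7.5 s -> 8 bpm).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    bpm = 60.0 / window_s
    return MinHR(bpm=bpm, bpm_int=int(math.ceil(bpm - 1e-12)))


def external_acceleration(
    burst: AccelBurst, gravity_mg: float = 1000.0, mode: str = "absolute"
) -> tuple[np.ndarray, float]:
    """External acceleration (EA) series and its burst average (AvgEA).

    Per sample, EA = |sqrt(ax^2 + ay^2 + az^2) - gravity_mg| in milli-g
    (``mode="signed"`` skips the absolute value).  The absolute-value
    default guarantees the non-negativity that the activity
    interpretation assumes.  AvgEA is the arithmetic mean over the burst.
    """
    if len(burst) == 0:
        raise ValueError("empty acceleration burst")
    if gravity_mg <= 0:
        raise ValueError("gravity_mg must be positive")
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    norm = np.sqrt(burst.ax ** 2 + burst.ay ** 2 + burst.az ** 2)
    ea = norm - gravity_mg
    if mode == "absolute":
        ea = np.abs(ea)
    return ea, float(ea.mean())
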