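"""Core containers shared by every stage of the pipeline.

A recording session is represented as a :class:`SessionBundle`: position
tracking samples, per-unit spike trains with region labels, continuous LFP
traces per region, an EMG trace, and session metadata.  Labeled time
intervals (laps, immobility, ripples, high-voltage spikes, EMG-detected head
twitches) are carried as :class:`IntervalSet` objects with half-open
``[start, end)`` semantics in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import signal as _signal

__all__ = [
    "ContinuousSignal",
    "SpikeTrain",
    "PositionTrace",
    "LinearizedTrace",
    "SpeedTrace",
    "IntervalSet",
    "SessionBundle",
    "bandpass",
    "gaussian_smooth",
]


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass filter (Butterworth, applied forward-backward).

    The same filter family is used for every band-pass step in the package
    (ripple 100-250 Hz, HVS/theta 6-12 Hz, EMG 20-60 Hz).
    """
    if hi * 2.0 >= fs:
        raise ValueError(f"sampling rate {fs} Hz cannot support a {hi} Hz band edge")
    sos = _signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def gaussian_smooth(x: np.ndarray, sigma_bins: float, truncate: float = 4.0) -> np.ndarray:
    """Gaussian smoothing with edge renormalization (kernel cut at +-truncate*sigma).

    Edge renormalization divides by the smoothed all-ones vector so that a
    constant input is returned unchanged near the boundaries.
    """
    from scipy.ndimage import gaussian_filter1d

    x = np.asarray(x, dtype=float)
    if sigma_bins <= 0:
        return x.copy()
    num = gaussian_filter1d(x, sigma_bins, mode="constant", cval=0.0, truncate=truncate)
    den = gaussian_filter1d(
        np.ones_like(x), sigma_bins, mode="constant", cval=0.0, truncate=truncate
    )
    return num / den


@dataclass
class ContinuousSignal:
    """Uniformly sampled continuous trace (LFP or EMG)."""

    label: str
    sampling_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def index_of(self, t: float | np.ndarray) -> np.ndarray:
        """Nearest sample index for time(s) ``t`` (clipped to the valid range)."""
        idx = np.rint((np.asarray(t) - self.t0) * self.sampling_rate).astype(int)
        return np.clip(idx, 0, self.samples.size - 1)


@dataclass
class SpikeTrain:
    unit_id: str
    region: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        self.times = np.sort(t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class PositionTrace:
    """Raw tracking samples (~33 Hz, cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("position time stamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("position coordinates must be finite")


@dataclass
class LinearizedTrace:
    """Positions projected onto the track skeleton.

    ``direction`` is +1 (trajectory 1, increasing arc length), -1
    (trajectory 2), or 0 where undefined (turns, immobility at the ends,
    projection outliers -- the white gaps of a linearized trajectory plot).
    """

    t: np.ndarray
    pos1d: np.ndarray
    direction: np.ndarray
    track_length: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos1d = np.asarray(self.pos1d, dtype=float)
        self.direction = np.asarray(self.direction, dtype=int)


@dataclass
class SpeedTrace:
    t: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)


class IntervalSet:
    """A labeled set of half-open time intervals ``[start, end)`` in seconds.

    Optionally carries per-interval peak times and arbitrary per-interval
    attribute arrays (amplitude, trough count, ...).
    """

    def __init__(
        self,
        label: str,
        start: Iterable[float] = (),
        end: Iterable[float] = (),
        peak: Iterable[float] | None = None,
        attrs: dict[str, np.ndarray] | None = None,
    ) -> None:
        self.label = label
        self.start = np.asarray(list(start), dtype=float)
        self.end = np.asarray(list(end), dtype=float)
        if self.start.size != self.end.size:
            raise ValueError("start and end must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("intervals must satisfy start < end")
        order = np.argsort(self.start, kind="stable")
        self.start = self.start[order]
        self.end = self.end[order]
        if peak is None:
            self.peak = np.full(self.start.size, np.nan)
        else:
            self.peak = np.asarray(list(peak), dtype=float)[order]
        self.attrs: dict[str, np.ndarray] = {}
        if attrs:
            for k, v in attrs.items():
                self.attrs[k] = np.asarray(v)[order]

    def __len__(self) -> int:
        return int(self.start.size)

    def __iter__(self):
        return iter(zip(self.start, self.end))

    @property
    def durations(self) -> np.ndarray:
        return self.end - self.start

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.end - self.start))

    def merge_gaps(self, max_gap: float) -> "IntervalSet":
        """Combine neighboring intervals whose gap is smaller than ``max_gap``.

        The merged interval's peak is the member peak with the largest
        absolute attribute ``amplitude`` if present, else the first peak.
        """
        if len(self) == 0:
            return IntervalSet(self.label)
        starts, ends, peaks = [self.start[0]], [self.end[0]], [self.peak[0]]
        amps = self.attrs.get("amplitude")
        best_amp = [amps[0]] if amps is not None else None
        for i in range(1, len(self)):
            if self.start[i] - ends[-1] < max_gap:
                ends[-1] = max(ends[-1], self.end[i])
                if amps is not None and abs(amps[i]) > abs(best_amp[-1]):
                    best_amp[-1] = amps[i]
                    peaks[-1] = self.peak[i]
            else:
                starts.append(self.start[i])
                ends.append(self.end[i])
                peaks.append(self.peak[i])
                if amps is not None:
                    best_amp.append(amps[i])
        attrs = {"amplitude": np.asarray(best_amp)} if amps is not None else None
        return IntervalSet(self.label, starts, ends, peaks, attrs)

    def intersect(self, other: "IntervalSet", label: str | None = None) -> "IntervalSet":
        """Interval-by-interval intersection of the two sets."""
        starts, ends = [], []
        j = 0
        for s, e in zip(self.start, self.end):
            for os_, oe in zip(other.start, other.end):
                lo, hi = max(s, os_), min(e, oe)
                if hi > lo:
                    starts.append(lo)
                    ends.append(hi)
        return IntervalSet(label or self.label, starts, ends)

    def clip(self, t0: float, t1: float) -> "IntervalSet":
        """Restrict to the window ``[t0, t1)``, truncating partial overlaps."""
        starts, ends, peaks = [], [], []
        keep_attrs: dict[str, list] = {k: [] for k in self.attrs}
        for i, (s, e) in enumerate(self):
            lo, hi = max(s, t0), min(e, t1)
            if hi > lo:
                starts.append(lo)
                ends.append(hi)
                peaks.append(self.peak[i])
                for k in self.attrs:
                    keep_attrs[k].append(self.attrs[k][i])
        attrs = {k: np.asarray(v) for k, v in keep_attrs.items()} if keep_attrs else None
        return IntervalSet(self.label, starts, ends, peaks, attrs)

    def complement(self, t0: float, t1: float, label: str = "complement") -> "IntervalSet":
        starts, ends = [], []
        cursor = t0
        for s, e in zip(self.start, self.end):
            s, e = max(s, t0), min(e, t1)
            if e <= s:
                continue
            if s > cursor:
                starts.append(cursor)
                ends.append(s)
            cursor = max(cursor, e)
        if cursor < t1:
            starts.append(cursor)
            ends.append(t1)
        return IntervalSet(label, starts, ends)

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: does each time fall inside some interval ``[s, e)``?"""
        times = np.asarray(times, dtype=float)
        if len(self) == 0 or times.size == 0:
            return np.zeros(times.shape, dtype=bool)
        idx = np.searchsorted(self.start, times, side="right") - 1
        ok = idx >= 0
        out = np.zeros(times.shape, dtype=bool)
        out[ok] = times[ok] < self.end[idx[ok]]
        return out

    def restrict(self, times: np.ndarray) -> np.ndarray:
        """Return the subset of ``times`` that fall inside the set."""
        return np.asarray(times)[self.contains(times)]


@dataclass
class SessionBundle:
    """One recording session: the unit of pipeline input."""

    positions: PositionTrace
    spikes: list[SpikeTrain]
    lfp: dict[str, ContinuousSignal]
    emg: ContinuousSignal
    metadata: dict = field(default_factory=dict)

    @property
    def session_label(self) -> str:
        return self.metadata.get("session_label", "?")

    @property
    def duration(self) -> float:
        return float(self.metadata.get("session_duration", self.positions.t[-1]))

    def spikes_by_region(self, region: str) -> list[SpikeTrain]:
        return [s for s in self.spikes if s.region == region]
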