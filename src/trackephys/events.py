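"""Ripple and high-voltage-spike (HVS) detection and coupling statistics.

Ripples: 100-250 Hz band, troughs beyond 6 baseline SDs, start/end at the
2.5 SD crossings of the analytic-signal amplitude, 30-400 ms duration,
< 30 ms gaps combined.  HVS: 6-12 Hz band, >= 4 troughs beyond 6 SD with
inter-trough intervals <= 250 ms, 2.5 SD edges, < 0.5 s gaps combined.
All thresholds are SD-relative, so both detectors are invariant to LFP
amplitude scaling.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks, hilbert

from .core import ContinuousSignal, IntervalSet, bandpass

__all__ = [
    "detect_ripples",
    "detect_hvs",
    "hvs_occupancy",
    "ripple_rate_within_hvs",
    "ripple_hvs_lfp_xcorr",
]


def _baseline_sd(filt: np.ndarray, mode: str, exclude: np.ndarray | None = None) -> float:
    if mode == "excluded" and exclude is not None and exclude.any():
        return float(np.std(filt[~exclude]))
    return float(np.std(filt))


def _edge_runs(env_above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end indices of contiguous True runs."""
    m = np.concatenate([[False], env_above, [False]])
    edges = np.flatnonzero(np.diff(m.astype(int)))
    return edges[::2], edges[1::2]


def detect_ripples(
    lfp_ca1: ContinuousSignal,
    band: tuple[float, float] = (100.0, 250.0),
    trough_sd: float = 6.0,
    edge_sd: float = 2.5,
    duration_range: tuple[float, float] = (0.030, 0.400),
    merge_gap: float = 0.030,
    baseline: str = "full",
) -> IntervalSet:
    """Ripple events from the CA1 LFP.

    Peak time is the deepest trough of the band-passed trace; per-event
    amplitude is that trough's magnitude in baseline-SD units.
    """
    fs = lfp_ca1.sampling_rate
    if fs < 2.4 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for the {band} Hz band")
    filt = bandpass(lfp_ca1.samples, fs, *band)
    env = np.abs(hilbert(filt))
    sd = _baseline_sd(filt, "full")
    events = _detect_from_troughs(filt, env, fs, lfp_ca1.t0, sd, trough_sd, edge_sd,
                                  min_troughs=1, max_iti=None, merge_gap=merge_gap)
    if baseline == "excluded" and len(events):
        mask = events.contains(lfp_ca1.times)
        sd = _baseline_sd(filt, "excluded", mask)
        events = _detect_from_troughs(filt, env, fs, lfp_ca1.t0, sd, trough_sd, edge_sd,
                                      min_troughs=1, max_iti=None, merge_gap=merge_gap)
    keep = (events.durations >= duration_range[0]) & (events.durations <= duration_range[1])
    return IntervalSet(
        "ripple",
        events.start[keep],
        events.end[keep],
        events.peak[keep],
        {k: v[keep] for k, v in events.attrs.items()},
    )


def detect_hvs(
    lfp_cortex: ContinuousSignal,
    band: tuple[float, float] = (6.0, 12.0),
    trough_sd: float = 6.0,
    edge_sd: float = 2.5,
    min_troughs: int = 4,
    max_inter_trough: float = 0.250,
    merge_gap: float = 0.5,
    baseline: str = "full",
) -> IntervalSet:
    """High-voltage spike-and-wave events from the cortical LFP.

    Attributes per event: n_troughs, amplitude (deepest trough, SD units),
    duration, and mean inter-trough frequency (n_troughs - 1 over the
    first-to-last trough span).
    """
    fs = lfp_cortex.sampling_rate
    if fs < 2.4 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for the {band} Hz band")
    filt = bandpass(lfp_cortex.samples, fs, *band)
    env = np.abs(hilbert(filt))
    sd = _baseline_sd(filt, "full")
    events = _detect_from_troughs(filt, env, fs, lfp_cortex.t0, sd, trough_sd, edge_sd,
                                  min_troughs, max_inter_trough, merge_gap)
    if baseline == "excluded" and len(events):
        mask = events.contains(lfp_cortex.times)
        sd = _baseline_sd(filt, "excluded", mask)
        events = _detect_from_troughs(filt, env, fs, lfp_cortex.t0, sd, trough_sd, edge_sd,
                                      min_troughs, max_inter_trough, merge_gap)
    events.label = "hvs"
    return events


def _detect_from_troughs(filt, env, fs, t0, sd, trough_sd, edge_sd,
                         min_troughs, max_iti, merge_gap):
    """Shared trough-grouping detector core.

    Troughs are minima of the signed filtered trace beyond ``trough_sd``
    SDs; for multi-trough events (HVS) consecutive troughs closer than
    ``max_iti`` are grouped and groups need >= ``min_troughs`` members.
    Start/end come from the 2.5 SD crossings of the analytic amplitude run
    containing the troughs.
    """
    trough_idx, _ = find_peaks(-filt, height=trough_sd * sd)
    label = "event"
    if trough_idx.size == 0:
        return IntervalSet(label)
    if max_iti is not None:
        iti = np.diff(trough_idx) / fs
        breaks = np.flatnonzero(iti > max_iti)
        groups = np.split(trough_idx, breaks + 1)
        groups = [g for g in groups if g.size >= min_troughs]
    else:
        groups = [np.array([i]) for i in trough_idx]
    if not groups:
        return IntervalSet(label)
    above = env > edge_sd * sd
    run_s, run_e = _edge_runs(above)
    starts, ends, peaks, n_tr, amps = [], [], [], [], []
    for g in groups:
        i0, i1 = g[0], g[-1]
        k0 = np.searchsorted(run_s, i0, side="right") - 1
        s = run_s[k0] if k0 >= 0 and run_e[k0] > i0 else i0
        k1 = np.searchsorted(run_s, i1, side="right") - 1
        e = run_e[k1] if k1 >= 0 and run_e[k1] > i1 else i1 + 1
        deepest = g[int(np.argmin(filt[g]))]
        starts.append(t0 + s / fs)
        ends.append(t0 + e / fs)
        peaks.append(t0 + deepest / fs)
        n_tr.append(g.size)
        amps.append(-filt[deepest] / sd)
    ev = IntervalSet(label, starts, ends, peaks,
                     {"n_troughs": np.asarray(n_tr), "amplitude": np.asarray(amps)})
    merged = _merge_events(ev, merge_gap, fs, t0, filt, sd, max_iti)
    return merged


def _merge_events(ev, merge_gap, fs, t0, filt, sd, max_iti):
    """Combine events separated by less than ``merge_gap``; recompute the
    peak/amplitude/trough count of merged events."""
    if len(ev) == 0:
        return ev
    starts, ends = [ev.start[0]], [ev.end[0]]
    for i in range(1, len(ev)):
        if ev.start[i] - ends[-1] < merge_gap:
            ends[-1] = max(ends[-1], ev.end[i])
        else:
            starts.append(ev.start[i])
            ends.append(ev.end[i])
    peaks, n_tr, amps, freqs, durs = [], [], [], [], []
    for s, e in zip(starts, ends):
        i0, i1 = int((s - t0) * fs), int((e - t0) * fs)
        seg = filt[i0:i1]
        tr_idx, _ = find_peaks(-seg, height=(6.0 * sd if max_iti is not None else 0.0))
        if tr_idx.size == 0:
            tr_idx = np.array([int(np.argmin(seg))])
        deepest = tr_idx[int(np.argmin(seg[tr_idx]))]
        peaks.append(s + deepest / fs)
        n_tr.append(tr_idx.size)
        amps.append(-seg[deepest] / sd)
        span = (tr_idx[-1] - tr_idx[0]) / fs
        freqs.append((tr_idx.size - 1) / span if span > 0 else np.nan)
        durs.append(e - s)
    return IntervalSet(
        ev.label, starts, ends, peaks,
        {
            "n_troughs": np.asarray(n_tr),
            "amplitude": np.asarray(amps),
            "frequency": np.asarray(freqs),
            "duration": np.asarray(durs),
        },
    )


def hvs_occupancy(
    hvs: IntervalSet, immobility: IntervalSet, window: tuple[float, float] | None = None
) -> float:
    """Percent of immobility time spent in HVS events, optionally restricted
    to a window (e.g., the first 30 minutes of POST)."""
    if window is not None:
        hvs = hvs.clip(*window)
        immobility = immobility.clip(*window)
    denom = immobility.total_duration
    if denom <= 0:
        return np.nan
    inter = hvs.intersect(immobility)
    return 100.0 * inter.total_duration / denom


def ripple_rate_within_hvs(ripples: IntervalSet, hvs: IntervalSet) -> float:
    """Ripples (by peak time) inside HVS events, per minute of HVS."""
    minutes = hvs.total_duration / 60.0
    if minutes <= 0:
        return np.nan
    peaks = ripples.peak[np.isfinite(ripples.peak)]
    n = int(np.sum(hvs.contains(peaks)))
    return n / minutes


def ripple_hvs_lfp_xcorr(
    lfp_ca1: ContinuousSignal,
    lfp_cortex: ContinuousSignal,
    windows: IntervalSet,
    max_lag: float = 1.0,
    out_fs: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of the ripple-band (100-250 Hz) CA1
    envelope against the HVS-band (6-12 Hz) cortical envelope within the
    given windows; positive lags mean the cortical envelope follows CA1.

    Returns (lags_s, mean correlation across usable windows)."""
    env_a = np.abs(hilbert(bandpass(lfp_ca1.samples, lfp_ca1.sampling_rate, 100.0, 250.0)))
    env_b = np.abs(hilbert(bandpass(lfp_cortex.samples, lfp_cortex.sampling_rate, 6.0, 12.0)))
    n_lag = int(round(max_lag * out_fs))
    lags = np.arange(-n_lag, n_lag + 1) / out_fs
    acc, n_used = np.zeros(lags.size), 0
    for s, e in windows:
        if e - s < 2 * max_lag:
            continue
        t = np.arange(s, e, 1.0 / out_fs)
        a = np.interp(t, lfp_ca1.times, env_a)
        b = np.interp(t, lfp_cortex.times, env_b)
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        r = np.empty(lags.size)
        for k, L in enumerate(range(-n_lag, n_lag + 1)):
            if L >= 0:
                x, y = a[: a.size - L], b[L:]
            else:
                x, y = a[-L:], b[: b.size + L]
            r[k] = np.mean(x * y) if x.size > 1 else np.nan
        acc += r
        n_used += 1
    if n_used == 0:
        return lags, np.full(lags.size, np.nan)
    return lags, acc / n_used
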