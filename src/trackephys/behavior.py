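"""Behavioral segmentation: linearization, speed, laps, immobility, eHT.

Raw tracking samples are projected onto the track skeleton to obtain a 1-D
position; instantaneous speed is Gaussian-smoothed (sigma 0.5 s); immobility
is thresholded at the mean speed around the reward sites (same threshold for
PRE and POST of one animal) with sub-0.5 s gaps merged; head twitches are
detected from the 20-60 Hz band of the neck EMG by an 8 SD multi-peak rule.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ContinuousSignal,
    IntervalSet,
    LinearizedTrace,
    PositionTrace,
    SpeedTrace,
    bandpass,
    gaussian_smooth,
)

__all__ = [
    "linearize",
    "compute_speed",
    "detect_immobility",
    "detect_stops",
    "segment_laps",
    "detect_eht",
    "behavior_summary",
]

DIRECTION_SPEED_THRESHOLD = 2.0  # cm/s on smoothed 1-D velocity
LAP_END_MARGIN = 10.0  # cm: a lap must reach within this of both ends
IMMOBILITY_MERGE_GAP = 0.5  # s
STOP_SPEED = 10.0  # cm/s, sustained-slow exclusion threshold
STOP_MIN_DURATION = 0.5  # s


def linearize(
    pos: PositionTrace,
    track_polyline: np.ndarray,
    projection_tolerance: float = 5.0,
    smooth_sigma_s: float = 0.5,
) -> LinearizedTrace:
    """Project tracking samples onto the track skeleton polyline.

    ``pos1d`` is the arc length of the nearest polyline point (0 at one
    reward end).  Direction is the sign of the smoothed 1-D velocity
    thresholded at +-2 cm/s; samples whose projection distance exceeds
    ``projection_tolerance`` (cm) are marked undefined -- the white gaps
    seen at sharp corner turns.
    """
    poly = np.asarray(track_polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2:
        raise ValueError("track polyline needs at least 2 vertices")
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pts = np.column_stack([pos.x, pos.y])

    best_d2 = np.full(pts.shape[0], np.inf)
    best_arc = np.zeros(pts.shape[0])
    for k in range(seg.shape[0]):
        rel = pts - poly[k]
        t = np.clip((rel @ seg[k]) / (seg_len[k] ** 2), 0.0, 1.0)
        proj = poly[k] + t[:, None] * seg[k]
        d2 = np.sum((pts - proj) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_arc[better] = cum[k] + t[better] * seg_len[k]

    dt = np.median(np.diff(pos.t)) if pos.t.size > 1 else 1.0
    vel = np.gradient(best_arc, pos.t)
    vel = gaussian_smooth(vel, smooth_sigma_s / dt)
    direction = np.zeros(pos.t.size, dtype=int)
    direction[vel > DIRECTION_SPEED_THRESHOLD] = 1
    direction[vel < -DIRECTION_SPEED_THRESHOLD] = -1
    direction[np.sqrt(best_d2) > projection_tolerance] = 0
    return LinearizedTrace(pos.t, best_arc, direction, float(cum[-1]))


def compute_speed(pos: PositionTrace, smooth_sigma_s: float = 0.5) -> SpeedTrace:
    """Instantaneous running speed, Gaussian-smoothed with sigma 0.5 s.

    Speed magnitude from centered finite differences of x/y; kernel
    truncated at +-4 sigma with edge renormalization.
    """
    if pos.t.size < 3:
        raise ValueError("need at least 3 position samples")
    if np.any(np.diff(pos.t) <= 0):
        raise ValueError("non-monotone time stamps")
    vx = np.gradient(pos.x, pos.t)
    vy = np.gradient(pos.y, pos.t)
    speed = np.hypot(vx, vy)
    dt = np.median(np.diff(pos.t))
    speed = gaussian_smooth(speed, smooth_sigma_s / dt)
    return SpeedTrace(pos.t, np.maximum(speed, 0.0))


def _runs_below(mask: np.ndarray, t: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs where ``mask`` is True, as (start, end) times."""
    if mask.size == 0 or not mask.any():
        return []
    m = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(m.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    dt = np.median(np.diff(t)) if t.size > 1 else 0.0
    out = []
    for s, e in zip(starts, ends):
        t0 = t[s]
        t1 = t[e - 1] + dt
        out.append((t0, t1))
    return out


def detect_immobility(
    speed: SpeedTrace,
    lin: LinearizedTrace,
    reward_sites: list[float],
    reward_radius: float = 10.0,
    threshold: float | None = None,
) -> tuple[IntervalSet, float]:
    """Immobility intervals and the speed threshold used.

    The threshold defaults to the mean speed within ``reward_radius`` cm of
    the reward sites; pass ``threshold`` explicitly to reuse one animal's
    PRE threshold for its POST session.  Neighboring sub-threshold periods
    with a gap < 0.5 s are combined.
    """
    if speed.t.size == 0:
        raise ValueError("empty speed trace")
    if threshold is None:
        near = np.zeros(lin.pos1d.size, dtype=bool)
        for site in reward_sites:
            near |= np.abs(lin.pos1d - site) <= reward_radius
        if not near.any():
            raise ValueError("no samples near the reward sites")
        threshold = float(np.mean(speed.speed[near]))
    runs = _runs_below(speed.speed < threshold, speed.t)
    iv = IntervalSet("immobility", *zip(*runs)) if runs else IntervalSet("immobility")
    iv = iv.merge_gaps(IMMOBILITY_MERGE_GAP)
    return iv, threshold


def detect_stops(speed: SpeedTrace) -> IntervalSet:
    """Sustained slow periods (< 10 cm/s for >= 0.5 s): the exclusion mask
    used by the rate analyses."""
    runs = _runs_below(speed.speed < STOP_SPEED, speed.t)
    runs = [(s, e) for s, e in runs if e - s >= STOP_MIN_DURATION]
    return IntervalSet("stop", *zip(*runs)) if runs else IntervalSet("stop")


def segment_laps(lin: LinearizedTrace) -> IntervalSet:
    """Laps: maximal periods during which pos1d travels from within 10 cm of
    one track end to within 10 cm of the other, one direction per lap."""
    T = lin.track_length
    lo, hi = LAP_END_MARGIN, T - LAP_END_MARGIN
    # crossing sequence of the two end zones
    zone = np.where(lin.pos1d <= lo, -1, np.where(lin.pos1d >= hi, 1, 0))
    starts, ends, dirs = [], [], []
    last_zone = 0
    last_leave_idx = 0
    for i in range(zone.size):
        z = zone[i]
        if z == 0:
            continue
        if last_zone == 0:
            last_zone = z
            last_leave_idx = i
        elif z == last_zone:
            last_leave_idx = i
        else:
            starts.append(lin.t[last_leave_idx])
            ends.append(lin.t[i])
            dirs.append(1 if z == 1 else -1)
            last_zone = z
            last_leave_idx = i
    return IntervalSet(
        "lap", starts, ends, attrs={"direction": np.asarray(dirs, dtype=int)}
    ) if starts else IntervalSet("lap")


def detect_eht(
    emg: ContinuousSignal,
    peak_threshold_sd: float = 8.0,
    edge_threshold_sd: float = 3.5,
    min_inter_peak: float = 0.1,
    max_group_gap: float = 0.5,
    band: tuple[float, float] = (20.0, 60.0),
    baseline: str = "full",
) -> IntervalSet:
    """EMG-detected head twitches.

    The EMG is band-pass filtered 20-60 Hz; an event needs >= 2 local maxima
    of the rectified trace above ``peak_threshold_sd`` baseline SDs with
    consecutive inter-peak times >= ``min_inter_peak`` (closer peaks count
    as one); start/end are the outermost 3.5 SD crossings bracketing the
    peak group.  Baseline SD is the full-session filtered-trace SD
    (``baseline="excluded"`` iterates once, excluding detected events).
    """
    if emg.sampling_rate < 2 * band[1]:
        raise ValueError("EMG sampling rate too low for the 20-60 Hz band")
    filt = bandpass(emg.samples, emg.sampling_rate, *band)
    sd = float(np.std(filt))
    events = _eht_pass(filt, emg, sd, peak_threshold_sd, edge_threshold_sd,
                       min_inter_peak, max_group_gap)
    if baseline == "excluded" and len(events):
        mask = np.ones(filt.size, dtype=bool)
        for s, e in events:
            mask[emg.index_of(s): emg.index_of(e) + 1] = False
        sd = float(np.std(filt[mask]))
        events = _eht_pass(filt, emg, sd, peak_threshold_sd, edge_threshold_sd,
                           min_inter_peak, max_group_gap)
    return events


def _eht_pass(filt, emg, sd, peak_sd, edge_sd, min_inter_peak, max_group_gap):
    from scipy.signal import find_peaks, hilbert

    rect = np.abs(filt)
    env = np.abs(hilbert(filt))  # start/end crossings use the amplitude envelope
    peak_idx, _ = find_peaks(rect, height=peak_sd * sd)
    if peak_idx.size == 0:
        return IntervalSet("eht")
    peak_t = emg.t0 + peak_idx / emg.sampling_rate
    # peaks closer than min_inter_peak count as one peak (keep the larger)
    merged_idx = [peak_idx[0]]
    for i in range(1, peak_idx.size):
        if peak_t[i] - (emg.t0 + merged_idx[-1] / emg.sampling_rate) < min_inter_peak:
            if rect[peak_idx[i]] > rect[merged_idx[-1]]:
                merged_idx[-1] = peak_idx[i]
        else:
            merged_idx.append(peak_idx[i])
    merged_idx = np.asarray(merged_idx)
    merged_t = emg.t0 + merged_idx / emg.sampling_rate
    # group distinct peaks separated by < max_group_gap into one event
    groups = []
    g = [0]
    for i in range(1, merged_idx.size):
        if merged_t[i] - merged_t[g[-1]] < max_group_gap:
            g.append(i)
        else:
            groups.append(g)
            g = [i]
    groups.append(g)
    above = env > edge_sd * sd
    starts, ends, peaks, amps = [], [], [], []
    for g in groups:
        if len(g) < 2:
            continue  # an eHT needs at least 2 suprathreshold peaks
        i0, i1 = merged_idx[g[0]], merged_idx[g[-1]]
        s = i0
        while s > 0 and above[s - 1]:
            s -= 1
        e = i1
        while e < above.size - 1 and above[e + 1]:
            e += 1
        best = g[int(np.argmax(rect[merged_idx[g]]))]
        starts.append(emg.t0 + s / emg.sampling_rate)
        ends.append(emg.t0 + (e + 1) / emg.sampling_rate)
        peaks.append(emg.t0 + merged_idx[best] / emg.sampling_rate)
        amps.append(rect[merged_idx[best]] / sd)
    if not starts:
        return IntervalSet("eht")
    return IntervalSet("eht", starts, ends, peaks, {"amplitude": np.asarray(amps)})


def behavior_summary(
    laps: IntervalSet,
    speed: SpeedTrace,
    immobility: IntervalSet,
    eht: IntervalSet,
    session_duration: float,
) -> dict:
    """Per-session behavioral report: lap rate, median running speed,
    percent immobile time, and HT rate (per min)."""
    minutes = session_duration / 60.0
    running_mask = ~immobility.contains(speed.t)
    run_speed = speed.speed[running_mask & (speed.speed >= STOP_SPEED)]
    return {
        "lap_rate_per_min": len(laps) / minutes if minutes else np.nan,
        "median_running_speed_cm_s": float(np.median(run_speed)) if run_speed.size else np.nan,
        "percent_immobile": 100.0 * immobility.total_duration / session_duration,
        "ht_rate_per_min": len(eht) / minutes if minutes else np.nan,
        "n_laps": len(laps),
    }
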