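"""Per-unit spatial firing metrics.

Rate curves are built per trajectory from lap-restricted, stop-excluded
spikes in 1 cm bins; spike-count and occupancy maps are smoothed separately
with a sigma = 3 bin Gaussian before division, and bins within ~10 cm of the
reward sites are masked.  On top of the curves: Skaggs spatial information
(bits/spike), PRE/POST stability and cross-trajectory directionality
(Pearson correlations), place-field detection (3 Hz peak, 10 %-of-peak
boundaries, < 5 cm gap merge), lap-by-lap speed-residual rates, and a burst
index (fraction of running spikes within 10 ms of another spike).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import IntervalSet, LinearizedTrace, SpeedTrace, SpikeTrain, gaussian_smooth

__all__ = [
    "RateCurve",
    "PlaceField",
    "SpeedRateRegression",
    "running_rate",
    "classify_units",
    "compute_rate_curve",
    "spatial_information",
    "curve_correlation",
    "stability",
    "directionality",
    "detect_place_fields",
    "lap_rate_speed",
    "residual_rates",
    "burst_index",
]

ACTIVE_RATE = 0.5  # Hz: minimum running rate for an active cell
INTERNEURON_RATE = 5.0  # Hz on both trajectories (CA1)
VC_EXCLUDE_RATE = 25.0  # Hz: very-high-rate VC units are excluded
FIELD_PEAK_THRESHOLD = 3.0  # Hz
FIELD_BOUNDARY_FRAC = 0.1
FIELD_MERGE_GAP = 5.0  # cm
BURST_WINDOW = 0.010  # s


@dataclass
class RateCurve:
    trajectory: int
    bin_edges: np.ndarray  # cm, 1 cm bins
    rate: np.ndarray  # Hz, smoothed; NaN where invalid
    occupancy: np.ndarray  # s per bin, smoothed
    raw_counts: np.ndarray
    raw_occupancy: np.ndarray
    valid: np.ndarray  # bool; False near reward sites or zero occupancy
    n_laps: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PlaceField:
    trajectory: int
    start_cm: float
    end_cm: float
    peak_rate: float
    peak_cm: float
    within_field_rate: float

    @property
    def length(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class SpeedRateRegression:
    slope: float  # Hz per cm/s
    intercept: float  # Hz
    lap_table: pd.DataFrame  # session, rate, speed, residual
    session_mean_residual: dict
    degenerate: bool = False


def _spikes_in_laps(
    st: SpikeTrain, laps: IntervalSet, stops: IntervalSet, trajectory: int | None = None
) -> np.ndarray:
    """Spike times inside the (optionally direction-selected) laps with
    sustained-stop periods removed."""
    t = st.times
    if trajectory is not None and "direction" in laps.attrs:
        keep = laps.attrs["direction"] == trajectory
        laps = IntervalSet("lap", laps.start[keep], laps.end[keep])
    mask = laps.contains(t) & ~stops.contains(t)
    return t[mask]


def _lap_time(laps: IntervalSet, stops: IntervalSet, trajectory: int | None = None) -> float:
    if trajectory is not None and "direction" in laps.attrs:
        keep = laps.attrs["direction"] == trajectory
        laps = IntervalSet("lap", laps.start[keep], laps.end[keep]) if keep.any() else IntervalSet("lap")
    total = laps.total_duration
    if len(laps) and len(stops):
        total -= laps.intersect(stops).total_duration
    return total


def running_rate(
    st: SpikeTrain, laps: IntervalSet, stops: IntervalSet, trajectory: int
) -> float:
    """Mean rate during one trajectory's laps, stops excluded."""
    T = _lap_time(laps, stops, trajectory)
    if T <= 0:
        return np.nan
    return _spikes_in_laps(st, laps, stops, trajectory).size / T


def classify_units(rate_table: pd.DataFrame) -> pd.DataFrame:
    """Classify units from a table of running rates.

    ``rate_table`` columns: unit_id, region, session, trajectory, rate.
    Returns one row per unit with class in {active, silent, interneuron,
    excluded}: interneurons (CA1) exceed 5 Hz on both trajectories; active
    cells exceed 0.5 Hz on >= 1 trajectory in >= 1 session; very-high-rate
    VC units (> 25 Hz) are excluded.
    """
    rows = []
    for (unit, region), g in rate_table.groupby(["unit_id", "region"], sort=True):
        rates = g["rate"].to_numpy()
        if not np.isfinite(rates).any():
            rows.append((unit, region, "excluded"))
            continue
        both_traj_min = (
            g.groupby("trajectory")["rate"].max().min()
            if g["trajectory"].nunique() > 1
            else np.nanmax(rates)
        )
        if region == "VC" and np.nanmax(rates) > VC_EXCLUDE_RATE:
            cls = "excluded"
        elif region == "CA1" and both_traj_min > INTERNEURON_RATE:
            cls = "interneuron"
        elif np.nanmax(rates) > ACTIVE_RATE:
            cls = "active"
        else:
            cls = "silent"
        rows.append((unit, region, cls))
    return pd.DataFrame(rows, columns=["unit_id", "region", "class"])


def compute_rate_curve(
    st: SpikeTrain,
    lin: LinearizedTrace,
    laps: IntervalSet,
    stops: IntervalSet,
    trajectory: int,
    track_length: float | None = None,
    reward_sites: list[float] | None = None,
    bin_size: float = 1.0,
    smooth_sigma_bins: float = 3.0,
    reward_radius: float = 10.0,
    smooth_mode: str = "separate",
) -> RateCurve:
    """Average firing rate across laps at each 1 cm position bin.

    ``smooth_mode="separate"`` smooths the spike-count and occupancy maps
    before dividing (the default); ``"ratio"`` smooths the unsmoothed ratio.
    """
    T = track_length if track_length is not None else lin.track_length
    edges = np.arange(0.0, T + bin_size, bin_size)
    nb = edges.size - 1
    if "direction" in laps.attrs:
        keep = laps.attrs["direction"] == trajectory
        sel = IntervalSet("lap", laps.start[keep], laps.end[keep]) if keep.any() else IntervalSet("lap")
    else:
        sel = laps
    n_laps = len(sel)
    dt = np.median(np.diff(lin.t)) if lin.t.size > 1 else 0.0
    occ_mask = sel.contains(lin.t) & ~stops.contains(lin.t)
    occ, _ = np.histogram(lin.pos1d[occ_mask], bins=edges)
    occ = occ * dt
    spk_t = _spikes_in_laps(st, laps, stops, trajectory)
    spk_pos = np.interp(spk_t, lin.t, lin.pos1d)
    counts, _ = np.histogram(spk_pos, bins=edges)

    valid = occ > 0
    if reward_sites:
        centers = 0.5 * (edges[:-1] + edges[1:])
        for site in reward_sites:
            valid &= np.abs(centers - site) > reward_radius
    if smooth_mode == "separate":
        occ_s = gaussian_smooth(occ.astype(float), smooth_sigma_bins)
        cnt_s = gaussian_smooth(counts.astype(float), smooth_sigma_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occ_s > 0, cnt_s / np.maximum(occ_s, 1e-12), np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(occ > 0, counts / np.maximum(occ, 1e-12), np.nan)
        rate = gaussian_smooth(np.nan_to_num(raw), smooth_sigma_bins)
        occ_s = occ.astype(float)
    rate = np.where(valid, rate, np.nan)
    return RateCurve(
        trajectory=trajectory,
        bin_edges=edges,
        rate=rate,
        occupancy=occ_s,
        raw_counts=counts,
        raw_occupancy=occ.astype(float),
        valid=valid,
        n_laps=n_laps,
    )


def spatial_information(curve: RateCurve) -> float:
    """Skaggs spatial information in bits per spike:
    ``SI = sum_i p_i (r_i / rbar) log2(r_i / rbar)`` with occupancy
    fractions p_i and mean rate ``rbar = sum_i p_i r_i``; zero-rate bins
    contribute zero.  Undefined (NaN) when the mean rate is zero."""
    ok = curve.valid & np.isfinite(curve.rate) & (curve.occupancy > 0)
    if not ok.any():
        return np.nan
    p = curve.occupancy[ok] / curve.occupancy[ok].sum()
    r = curve.rate[ok]
    rbar = float(np.sum(p * r))
    if rbar <= 0:
        return np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(r > 0, p * (r / rbar) * np.log2(r / rbar, where=r > 0, out=np.zeros_like(r)), 0.0)
    return float(np.sum(terms))


def curve_correlation(curve_a: RateCurve, curve_b: RateCurve, min_bins: int = 10) -> float:
    """Pearson correlation between two rate curves over jointly valid bins;
    NaN when fewer than ``min_bins`` bins overlap or either curve is
    constant on the overlap."""
    if not np.array_equal(curve_a.bin_edges, curve_b.bin_edges):
        raise ValueError("rate curves must share bin edges")
    ok = (
        curve_a.valid & curve_b.valid
        & np.isfinite(curve_a.rate) & np.isfinite(curve_b.rate)
    )
    if ok.sum() < min_bins:
        return np.nan
    a, b = curve_a.rate[ok], curve_b.rate[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(sstats.pearsonr(a, b)[0])


def stability(curve_pre: RateCurve, curve_post: RateCurve) -> float:
    """PRE/POST correlation of the same trajectory's rate curves."""
    return curve_correlation(curve_pre, curve_post)


def directionality(curve_traj1: RateCurve, curve_traj2: RateCurve) -> float:
    """Correlation between the two trajectories' rate curves in one session;
    a higher correlation means lower directionality.  Both curves are binned
    on the same physical track positions, so no realignment is needed."""
    return curve_correlation(curve_traj1, curve_traj2)


def detect_place_fields(
    curve: RateCurve,
    peak_threshold: float = FIELD_PEAK_THRESHOLD,
    boundary_frac: float = FIELD_BOUNDARY_FRAC,
    merge_gap: float = FIELD_MERGE_GAP,
) -> list[PlaceField]:
    """Place fields of a smoothed rate curve.

    Each local peak >= 3 Hz is extended outward to where the rate first
    drops below 10 % of that peak (or becomes invalid); overlapping fields
    and fields separated by < 5 cm are combined, the merged field keeping
    the largest member peak.
    """
    from scipy.signal import find_peaks

    r = np.where(curve.valid & np.isfinite(curve.rate), curve.rate, 0.0)
    centers = curve.centers
    peak_idx, _ = find_peaks(r, height=peak_threshold)
    # a monotone-edge maximum at the valid boundary also counts as a peak
    fields: list[list[float]] = []
    for pk in peak_idx:
        thr = boundary_frac * r[pk]
        i = pk
        while i > 0 and r[i - 1] >= thr and curve.valid[i - 1]:
            i -= 1
        j = pk
        while j < r.size - 1 and r[j + 1] >= thr and curve.valid[j + 1]:
            j += 1
        fields.append([centers[i], centers[j], r[pk], centers[pk]])
    if not fields:
        return []
    fields.sort(key=lambda f: f[0])
    merged = [fields[0]]
    for f in fields[1:]:
        if f[0] - merged[-1][1] < merge_gap:
            m = merged[-1]
            m[1] = max(m[1], f[1])
            if f[2] > m[2]:
                m[2], m[3] = f[2], f[3]
        else:
            merged.append(f)
    bin_size = curve.bin_edges[1] - curve.bin_edges[0]
    out = []
    for s, e, pk, pc in merged:
        inside = (centers >= s) & (centers <= e) & curve.valid & np.isfinite(curve.rate)
        wfr = float(np.mean(curve.rate[inside])) if inside.any() else np.nan
        out.append(
            PlaceField(
                trajectory=curve.trajectory,
                start_cm=float(s - bin_size / 2),
                end_cm=float(e + bin_size / 2),
                peak_rate=float(pk),
                peak_cm=float(pc),
                within_field_rate=wfr,
            )
        )
    return out


def lap_rate_speed(
    st: SpikeTrain,
    laps_by_session: dict[str, IntervalSet],
    lin_by_session: dict[str, LinearizedTrace],
    speed_by_session: dict[str, SpeedTrace],
    stops_by_session: dict[str, IntervalSet],
    trajectory: int,
    spikes_by_session: dict[str, SpikeTrain] | None = None,
    field: PlaceField | None = None,
) -> pd.DataFrame:
    """Lap-by-lap mean firing rate and mean running speed.

    With a ``field``, both rate and speed are computed only while the animal
    is within the field boundaries (the within-field variant).  When PRE and
    POST carry separate spike trains, pass them via ``spikes_by_session``.
    """
    rows = []
    for session, laps in laps_by_session.items():
        lin = lin_by_session[session]
        spd = speed_by_session[session]
        stops = stops_by_session[session]
        train = spikes_by_session[session] if spikes_by_session else st
        if "direction" in laps.attrs:
            keep = laps.attrs["direction"] == trajectory
            sel_s, sel_e = laps.start[keep], laps.end[keep]
        else:
            sel_s, sel_e = laps.start, laps.end
        dt = np.median(np.diff(lin.t)) if lin.t.size > 1 else 0.0
        for s, e in zip(sel_s, sel_e):
            m = (lin.t >= s) & (lin.t < e) & ~stops.contains(lin.t)
            if field is not None:
                m &= (lin.pos1d >= field.start_cm) & (lin.pos1d <= field.end_cm)
            T = m.sum() * dt
            if T <= 0:
                continue
            spk = train.times[(train.times >= s) & (train.times < e)]
            spk = spk[~stops.contains(spk)]
            if field is not None:
                spk_pos = np.interp(spk, lin.t, lin.pos1d)
                spk = spk[(spk_pos >= field.start_cm) & (spk_pos <= field.end_cm)]
            rows.append((session, spk.size / T, float(np.mean(spd.speed[m]))))
    return pd.DataFrame(rows, columns=["session", "rate", "speed"])


def residual_rates(lap_table: pd.DataFrame, min_laps: int = 4) -> SpeedRateRegression:
    """Ordinary least squares of lap rate on lap speed, fitted jointly over
    all sessions' laps; residuals are averaged per session.  With identical
    speeds the slope is undefined: falls back to slope 0, intercept = mean
    rate, and is flagged degenerate."""
    df = lap_table.copy()
    if len(df) < min_laps:
        raise ValueError(f"need at least {min_laps} laps, got {len(df)}")
    s = df["speed"].to_numpy()
    r = df["rate"].to_numpy()
    degenerate = np.std(s) == 0
    if degenerate:
        k, b = 0.0, float(np.mean(r))
    else:
        k, b = np.polyfit(s, r, 1)
    df["residual"] = r - (k * s + b)
    means = {sess: float(g["residual"].mean()) for sess, g in df.groupby("session")}
    return SpeedRateRegression(float(k), float(b), df, means, bool(degenerate))


def burst_index(running_spikes: np.ndarray, window: float = BURST_WINDOW) -> float:
    """Fraction of running spikes occurring within 10 ms of another spike
    (preceding or following)."""
    t = np.sort(np.asarray(running_spikes, dtype=float))
    if t.size < 2:
        return np.nan
    isi = np.diff(t)
    near = np.zeros(t.size, dtype=bool)
    near[:-1] |= isi <= window
    near[1:] |= isi <= window
    return float(np.mean(near))
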