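"""Shuffle-normalized pairwise spike correlations and triggered averages.

The normalized cross-correlogram of two spike trains is computed within a
set of behavioral events (running laps, ripples, or ripple-centered
windows): spikes are binned at 10 ms inside each event, a circular
cross-correlogram is accumulated across events, and the null distribution
comes from 200 event-wise circular shifts of both trains independently.
The per-lag Z-score of the observed against the shuffle mean/SD is the
normalized correlation; coactivity is its average around lag zero in a
context-dependent window (running +-100 ms, within-ripple CA1 +-50 ms,
CA1-VC around ripples +-100 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .core import ContinuousSignal, IntervalSet, LinearizedTrace, gaussian_smooth

__all__ = [
    "CONTEXTS",
    "NormalizedCorrelogram",
    "normalized_xcorr",
    "coactivity",
    "reactivation",
    "mua_trace",
    "mua_xcorr",
    "TriggeredAverage",
    "triggered_average",
    "ripple_triggered_vc_mua",
    "ripple_windows",
]

XCORR_BIN = 0.010  # s
N_SHUFFLES = 200

#: per-context (max display lag s, boxcar smoothing half-width bins,
#: coactivity half-window s)
CONTEXTS = {
    "running": (0.5, 10, 0.100),
    "ripple_ca1": (0.1, 4, 0.050),
    "ripple_ca1vc": (0.2, 4, 0.100),
    "hvs": (0.2, 4, 0.100),
}


@dataclass
class NormalizedCorrelogram:
    lags: np.ndarray  # s, bin centers, symmetric about 0
    z: np.ndarray  # per-lag Z-score; NaN where shuffle SD is 0
    observed: np.ndarray
    shuffle_mean: np.ndarray
    shuffle_sd: np.ndarray
    n_shuffles: int
    context: str


def _linear_xcorr_batch(A: np.ndarray, B: np.ndarray, n_lag: int) -> np.ndarray:
    """Linear spike-count cross-correlograms for a batch of binned trains.

    ``A``, ``B``: (k, L) count arrays; returns (k, 2*n_lag+1) with
    ``out[:, n_lag+m] = sum_t A[:, t] * B[:, t+m]`` (no wrap-around)."""
    k, L = A.shape
    out = np.zeros((k, 2 * n_lag + 1))
    for m in range(-n_lag, n_lag + 1):
        if m >= L or -m >= L:
            continue
        if m >= 0:
            out[:, m + n_lag] = np.einsum("kt,kt->k", A[:, : L - m], B[:, m:])
        else:
            out[:, m + n_lag] = np.einsum("kt,kt->k", A[:, -m:], B[:, : L + m])
    return out


def _boxcar(x: np.ndarray, half: int) -> np.ndarray:
    """Nearest-neighbor averaging over +-half bins, edges renormalized."""
    if half <= 0:
        return x
    k = np.ones(2 * half + 1)
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def normalized_xcorr(
    train_a: np.ndarray,
    train_b: np.ndarray,
    events: IntervalSet,
    context: str = "running",
    n_shuffles: int = N_SHUFFLES,
    bin_size: float = XCORR_BIN,
    rng: np.random.Generator | None = None,
    method: str = "rotate",
) -> NormalizedCorrelogram:
    """Shuffle-normalized spike-count cross-correlogram within events.

    Both trains are restricted to the events; each of the ``n_shuffles``
    null draws circularly shifts the two trains independently within every
    event.  ``method="rotate"`` quantizes the shift to whole bins and uses
    the circular-correlogram rotation identity (fast, the default);
    ``method="rebin"`` shifts spike times by continuous uniform offsets and
    re-bins each shuffle.  Positive lags mean train_b fires after train_a.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if len(events) == 0:
        raise ValueError("need at least one event")
    rng = rng or np.random.default_rng(0)
    max_lag, smooth_half, _ = CONTEXTS[context]
    n_lag = int(round(max_lag / bin_size))
    lag_idx = np.arange(-n_lag, n_lag + 1)
    obs = np.zeros(lag_idx.size)
    shuf = np.zeros((n_shuffles, lag_idx.size))
    # events much longer than the lag span use the circular correlogram and
    # the exact rotation identity for the event-wise shift null (edge
    # effects O(lag/length) are negligible there); shorter events use the
    # literal linear correlogram, recomputed per shuffle
    circular_min_len = 4 * (2 * n_lag + 1)

    ta_all = np.asarray(train_a, dtype=float)
    tb_all = np.asarray(train_b, dtype=float)
    for s, e in events:
        L = max(2, int(np.ceil((e - s) / bin_size)))
        a_t = ta_all[(ta_all >= s) & (ta_all < e)] - s
        b_t = tb_all[(tb_all >= s) & (tb_all < e)] - s
        if a_t.size == 0 or b_t.size == 0:
            continue
        if method == "rebin":
            a = np.bincount(np.minimum((a_t / bin_size).astype(int), L - 1), minlength=L)
            b = np.bincount(np.minimum((b_t / bin_size).astype(int), L - 1), minlength=L)
            obs += _linear_xcorr_batch(a[None, :], b[None, :], n_lag)[0]
            span = e - s
            for k in range(n_shuffles):
                ua, ub = rng.uniform(0, span, 2)
                a2 = np.bincount(
                    np.minimum((np.mod(a_t + ua, span) / bin_size).astype(int), L - 1),
                    minlength=L)
                b2 = np.bincount(
                    np.minimum((np.mod(b_t + ub, span) / bin_size).astype(int), L - 1),
                    minlength=L)
                shuf[k] += _linear_xcorr_batch(a2[None, :], b2[None, :], n_lag)[0]
            continue
        a = np.bincount(np.minimum((a_t / bin_size).astype(int), L - 1), minlength=L)
        b = np.bincount(np.minimum((b_t / bin_size).astype(int), L - 1), minlength=L)
        ka = rng.integers(0, L, n_shuffles)
        kb = rng.integers(0, L, n_shuffles)
        if L >= circular_min_len:
            C = np.fft.irfft(np.conj(np.fft.rfft(a, L)) * np.fft.rfft(b, L), L)
            obs += C[lag_idx % L]
            delta = (ka - kb) % L
            shuf += C[(lag_idx[None, :] + delta[:, None]) % L]
        else:
            obs += _linear_xcorr_batch(a[None, :], b[None, :], n_lag)[0]
            idx = np.arange(L)
            A = a[(idx[None, :] - ka[:, None]) % L]
            B = b[(idx[None, :] - kb[:, None]) % L]
            shuf += _linear_xcorr_batch(A, B, n_lag)

    obs_s = _boxcar(obs, smooth_half)
    shuf_s = np.vstack([_boxcar(row, smooth_half) for row in shuf])
    mu = shuf_s.mean(axis=0)
    sd = shuf_s.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs_s - mu) / sd, np.nan)
    return NormalizedCorrelogram(
        lags=lag_idx * bin_size,
        z=z,
        observed=obs_s,
        shuffle_mean=mu,
        shuffle_sd=sd,
        n_shuffles=n_shuffles,
        context=context,
    )


def coactivity(correlogram: NormalizedCorrelogram) -> float:
    """Average Z around lag zero in the context's window."""
    _, _, half_window = CONTEXTS[correlogram.context]
    sel = np.abs(correlogram.lags) <= half_window + 1e-9
    vals = correlogram.z[sel]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else np.nan


def ripple_windows(ripples: IntervalSet, half: float = 1.0) -> IntervalSet:
    """[-1, 1] s windows around ripple peak times (for CA1-VC correlograms)."""
    peaks = ripples.peak[np.isfinite(ripples.peak)]
    return IntervalSet("ripple_window", peaks - half, peaks + half)


def reactivation(
    coact_running: np.ndarray, coact_events: np.ndarray, min_pairs: int = 10
) -> tuple[float, float, int]:
    """Awake reactivation: correlation across cell pairs of running
    coactivity against within-ripple coactivity.  Returns (r, p, n)."""
    a = np.asarray(coact_running, dtype=float)
    b = np.asarray(coact_events, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_pairs:
        return np.nan, np.nan, int(ok.sum())
    r, p = sstats.pearsonr(a[ok], b[ok])
    return float(r), float(p), int(ok.sum())


def mua_trace(
    spike_trains: list[np.ndarray],
    t0: float,
    t1: float,
    bin_size: float = 0.010,
    smooth_sigma_bins: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-unit activity: all spikes of one region counted in 10 ms bins,
    normalized to [0, 1], Gaussian-smoothed (sigma 3 bins).

    Returns (bin_centers, mua)."""
    edges = np.arange(t0, t1 + bin_size, bin_size)
    allspk = np.concatenate([np.asarray(t) for t in spike_trains]) if spike_trains else np.empty(0)
    counts, _ = np.histogram(allspk, bins=edges)
    counts = counts.astype(float)
    peak = counts.max()
    if peak > 0:
        counts /= peak
    mua = gaussian_smooth(counts, smooth_sigma_bins)
    return 0.5 * (edges[:-1] + edges[1:]), mua


def mua_xcorr(
    mua_t: np.ndarray,
    mua_ca1: np.ndarray,
    mua_vc: np.ndarray,
    running: IntervalSet,
    max_lag: float = 1.0,
    min_period: float = 2.0,
) -> "TriggeredAverage":
    """Pearson cross-correlation between CA1 and VC MUA traces at each lag
    within +-1 s, computed per running period (>= 2 s, no immobility) and
    averaged across periods; positive lags mean VC follows CA1."""
    bin_size = mua_t[1] - mua_t[0]
    n_lag = int(round(max_lag / bin_size))
    lags = np.arange(-n_lag, n_lag + 1) * bin_size
    rows = []
    for s, e in running:
        if e - s < min_period:
            continue
        sel = (mua_t >= s) & (mua_t < e)
        a, b = mua_ca1[sel], mua_vc[sel]
        if a.size <= 2 * n_lag + 2 or np.std(a) == 0 or np.std(b) == 0:
            continue
        r = np.empty(lags.size)
        for k, L in enumerate(range(-n_lag, n_lag + 1)):
            if L >= 0:
                x, y = a[: a.size - L], b[L:]
            else:
                x, y = a[-L:], b[: b.size + L]
            if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
                r[k] = np.nan
                continue
            r[k] = np.corrcoef(x, y)[0, 1]
        rows.append(r)
    if not rows:
        return TriggeredAverage(lags, np.full(lags.size, np.nan),
                                np.full(lags.size, np.nan), 0, "mua_xcorr")
    M = np.vstack(rows)
    mean = np.nanmean(M, axis=0)
    se = np.nanstd(M, axis=0, ddof=1) / np.sqrt(M.shape[0]) if M.shape[0] > 1 else np.full(lags.size, np.nan)
    return TriggeredAverage(lags, mean, se, M.shape[0], "mua_xcorr")


@dataclass
class TriggeredAverage:
    lags: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_events: int
    label: str

    @property
    def peak(self) -> tuple[float, float]:
        """(peak value, peak lag)."""
        if not np.isfinite(self.mean).any():
            return np.nan, np.nan
        i = int(np.nanargmax(self.mean))
        return float(self.mean[i]), float(self.lags[i])


def ripple_triggered_vc_mua(
    mua_t: np.ndarray,
    mua_vc: np.ndarray,
    ripple_peaks: np.ndarray,
    max_lag: float = 0.050,
    baseline_windows: tuple = ((-0.120, -0.100), (0.100, 0.120)),
) -> TriggeredAverage:
    """VC MUA triggered on ripple peak times, at lags within +-50 ms
    (resolving peaks within an HVS cycle of ~100 ms), expressed relative to
    the mean over the two flanking baseline windows."""
    bin_size = mua_t[1] - mua_t[0]
    n_lag = int(round(max_lag / bin_size))
    lags = np.arange(-n_lag, n_lag + 1) * bin_size
    lo = min(w[0] for w in baseline_windows)
    hi = max(w[1] for w in baseline_windows)
    rows = []
    for t in np.asarray(ripple_peaks, dtype=float):
        if t + lo < mua_t[0] or t + hi > mua_t[-1]:
            continue
        vals = np.interp(t + lags, mua_t, mua_vc)
        base = []
        for w0, w1 in baseline_windows:
            tt = np.arange(t + w0, t + w1 + bin_size / 2, bin_size)
            base.append(np.interp(tt, mua_t, mua_vc))
        rows.append(vals - np.mean(np.concatenate(base)))
    if not rows:
        return TriggeredAverage(lags, np.full(lags.size, np.nan),
                                np.full(lags.size, np.nan), 0, "ripple_triggered_vc_mua")
    M = np.vstack(rows)
    mean = M.mean(axis=0)
    se = (M.std(axis=0, ddof=1) / np.sqrt(M.shape[0])
          if M.shape[0] > 1 else np.full(lags.size, np.nan))
    return TriggeredAverage(lags, mean, se, M.shape[0], "ripple_triggered_vc_mua")


def triggered_average(
    kind: str,
    data,
    trigger_times: np.ndarray,
    window: tuple[float, float],
    bin_size: float = 0.050,
    session_duration: float | None = None,
) -> TriggeredAverage:
    """Event-triggered average of a signal, 1-D position, or unit rates.

    ``kind``:
      * ``"signal"`` -- ``data`` is a ContinuousSignal (or a SpeedTrace-like
        object with ``t``/``speed``); values are sampled at each lag.
      * ``"position"`` -- ``data`` is a LinearizedTrace; each trigger's
        position at lag 0 is re-zeroed to 0 cm.
      * ``"rate"`` -- ``data`` is a list of spike-time arrays; per-lag rates
        are averaged across cells, then across triggers.

    Triggers whose window is not fully inside the session are dropped.
    """
    trig = np.sort(np.asarray(trigger_times, dtype=float))
    lags = np.arange(window[0] + bin_size / 2, window[1], bin_size)
    if session_duration is not None:
        trig = trig[(trig + window[0] >= 0) & (trig + window[1] <= session_duration)]
    if trig.size == 0:
        return TriggeredAverage(lags, np.full(lags.size, np.nan),
                                np.full(lags.size, np.nan), 0, kind)
    rows = []
    for t in trig:
        tt = t + lags
        if kind == "signal":
            if isinstance(data, ContinuousSignal):
                vals = data.samples[data.index_of(tt)]
            else:
                vals = np.interp(tt, data.t, data.speed)
        elif kind == "position":
            assert isinstance(data, LinearizedTrace)
            pos = np.interp(tt, data.t, data.pos1d)
            vals = pos - np.interp(t, data.t, data.pos1d)
        elif kind == "rate":
            edges = t + np.arange(window[0], window[1] + bin_size / 2, bin_size)
            per_cell = [np.histogram(spk, bins=edges)[0] / bin_size for spk in data]
            vals = np.mean(per_cell, axis=0)
        else:
            raise ValueError(f"unknown kind {kind!r}")
        rows.append(vals)
    M = np.vstack(rows)
    mean = M.mean(axis=0)
    se = M.std(axis=0, ddof=1) / np.sqrt(M.shape[0]) if M.shape[0] > 1 else np.full(lags.size, np.nan)
    return TriggeredAverage(lags, mean, se, M.shape[0], kind)
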