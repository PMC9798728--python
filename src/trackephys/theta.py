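"""Theta-band measures: speed-banded multitaper spectra, CA1-VC coherence,
spike theta-phase assignment, phase precession, theta sequences.

Phases follow the peak/trough anchoring convention: a filtered-theta peak is
0/360 degrees, a trough 180 degrees, with linear interpolation in between
(not the analytic-signal angle).  Phase precession is quantified by the
maximum linear correlation between (slope-unwrapped) phase and position
within a place field, scanned over candidate slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.signal import find_peaks
from scipy.signal.windows import dpss

from .core import ContinuousSignal, IntervalSet, SpeedTrace, bandpass, gaussian_smooth

__all__ = [
    "SpeedBandSpectrum",
    "speed_banded_psd",
    "theta_coherence",
    "assign_theta_phase",
    "phase_precession",
    "theta_sequences",
    "SPEED_BANDS",
]

SPEED_BANDS = ((0.0, 20.0), (20.0, 40.0), (40.0, 60.0), (60.0, np.inf))
THETA_BAND = (6.0, 10.0)
SEGMENT_LEN = 2.0  # s, multitaper analysis window
TIME_BANDWIDTH = 3.0
N_TAPERS = 5
FREQ_RESOLUTION = 0.25  # Hz, achieved by zero-padding


@dataclass
class SpeedBandSpectrum:
    speed_band: tuple[float, float]
    freqs: np.ndarray
    psd: np.ndarray
    theta_peak_freq: float
    theta_power: float
    n_segments: int


def _taper_bank(n: int):
    w = dpss(n, TIME_BANDWIDTH, N_TAPERS)
    w = w / np.sqrt(np.sum(w**2, axis=1, keepdims=True))
    return w


def _mt_spectra(x: np.ndarray, fs: float, nfft: int) -> np.ndarray:
    """Per-taper one-sided spectra of one segment (tapers x freqs)."""
    w = _taper_bank(x.size)
    xd = x - x.mean()
    return np.fft.rfft(w * xd[None, :], n=nfft, axis=1)


def _psd_from_spectra(spec: np.ndarray, fs: float) -> np.ndarray:
    p = np.mean(np.abs(spec) ** 2, axis=0) * 2.0 / fs
    p[0] /= 2.0
    if spec.shape[1] % 2 == 1:  # nfft even: last bin is Nyquist
        p[-1] /= 2.0
    return p


def _qualifying_segments(
    speed: SpeedTrace, laps: IntervalSet, band: tuple[float, float], min_len: float
):
    """Contiguous lap periods whose speed stays within the band for at least
    ``min_len`` s, split into analysis windows of SEGMENT_LEN."""
    in_lap = laps.contains(speed.t)
    in_band = (speed.speed >= band[0]) & (speed.speed < band[1]) & in_lap
    m = np.concatenate([[False], in_band, [False]])
    edges = np.flatnonzero(np.diff(m.astype(int)))
    out = []
    for s, e in zip(edges[::2], edges[1::2]):
        t0, t1 = speed.t[s], speed.t[e - 1]
        if t1 - t0 >= min_len:
            k = t0
            while k + SEGMENT_LEN <= t1 + 1e-9:
                out.append((k, k + SEGMENT_LEN))
                k += SEGMENT_LEN
    return out


def speed_banded_psd(
    lfp: ContinuousSignal,
    speed: SpeedTrace,
    laps: IntervalSet,
    bands=SPEED_BANDS,
    min_len: float = 2.0,
) -> list[SpeedBandSpectrum]:
    """Multitaper PSD of the LFP per running-speed band.

    Bands without a single qualifying >= 2 s segment are omitted (not every
    speed range occurs in every session).  Theta peak frequency is the PSD
    argmax on the 6-10 Hz range of the 0.25 Hz grid; theta power is the
    band-integrated PSD.
    """
    fs = lfp.sampling_rate
    nfft = int(round(fs / FREQ_RESOLUTION))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    out = []
    for band in bands:
        segs = _qualifying_segments(speed, laps, band, min_len)
        if not segs:
            continue
        acc = np.zeros(freqs.size)
        for s, e in segs:
            i0, i1 = lfp.index_of(s), lfp.index_of(e)
            acc += _psd_from_spectra(_mt_spectra(lfp.samples[i0:i1], fs, nfft), fs)
        psd = acc / len(segs)
        sel = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
        pk = float(freqs[sel][np.argmax(psd[sel])])
        power = float(np.trapezoid(psd[sel], freqs[sel]))
        out.append(SpeedBandSpectrum(band, freqs, psd, pk, power, len(segs)))
    return out


def theta_coherence(
    lfp_a: ContinuousSignal,
    lfp_b: ContinuousSignal,
    running: IntervalSet,
    band: tuple[float, float] = THETA_BAND,
) -> float:
    """Magnitude-squared coherence between the two LFPs during running,
    averaged over the theta band (multitaper, 2 s windows)."""
    fs = lfp_a.sampling_rate
    if lfp_b.sampling_rate != fs:
        raise ValueError("signals must share a sampling rate")
    nfft = int(round(fs / FREQ_RESOLUTION))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    Sxx = np.zeros(freqs.size)
    Syy = np.zeros(freqs.size)
    Sxy = np.zeros(freqs.size, dtype=complex)
    n_seg = 0
    for s, e in running:
        k = s
        while k + SEGMENT_LEN <= e + 1e-9:
            i0, i1 = lfp_a.index_of(k), lfp_a.index_of(k + SEGMENT_LEN)
            A = _mt_spectra(lfp_a.samples[i0:i1], fs, nfft)
            B = _mt_spectra(lfp_b.samples[i0:i1], fs, nfft)
            Sxx += np.mean(np.abs(A) ** 2, axis=0)
            Syy += np.mean(np.abs(B) ** 2, axis=0)
            Sxy += np.mean(A * np.conj(B), axis=0)
            n_seg += 1
            k += SEGMENT_LEN
    if n_seg == 0:
        return np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(Sxy) ** 2 / (Sxx * Syy)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.nanmean(coh[sel]))


def assign_theta_phase(
    spike_times: np.ndarray,
    lfp: ContinuousSignal,
    running: IntervalSet,
    band: tuple[float, float] = THETA_BAND,
) -> np.ndarray:
    """Theta phase (degrees, [0, 360)) of each spike during running.

    The LFP is filtered 6-10 Hz; peaks anchor 0/360 degrees and troughs 180,
    with piecewise-linear interpolation between consecutive anchors.  Spikes
    outside running or outside anchored cycles get NaN.
    """
    fs = lfp.sampling_rate
    filt = bandpass(lfp.samples, fs, *band)
    min_dist = int(fs / (band[1] * 2.5))
    pk, _ = find_peaks(filt, distance=min_dist)
    tr, _ = find_peaks(-filt, distance=min_dist)
    anchors = np.concatenate([pk, tr])
    kind = np.concatenate([np.zeros(pk.size, dtype=int), np.ones(tr.size, dtype=int)])
    order = np.argsort(anchors)
    anchors, kind = anchors[order], kind[order]
    # enforce strict peak/trough alternation (keep the first of any repeat)
    keep = np.concatenate([[True], kind[1:] != kind[:-1]])
    anchors, kind = anchors[keep], kind[keep]
    if anchors.size < 2:
        return np.full(np.asarray(spike_times).size, np.nan)
    # unwrapped phase: each step peak->trough or trough->peak adds 180 deg
    phase0 = 0.0 if kind[0] == 0 else 180.0
    unwrapped = phase0 + 180.0 * np.arange(anchors.size)
    anchor_t = lfp.t0 + anchors / fs
    st = np.asarray(spike_times, dtype=float)
    phases = np.full(st.size, np.nan)
    ok = (st >= anchor_t[0]) & (st <= anchor_t[-1]) & running.contains(st)
    phases[ok] = np.mod(np.interp(st[ok], anchor_t, unwrapped), 360.0)
    return phases


def phase_precession(
    phases: np.ndarray,
    positions: np.ndarray,
    slope_range: tuple[float, float] = (-15.0, 15.0),
    slope_step: float = 0.1,
    min_spikes: int = 20,
) -> tuple[float, float]:
    """Circular-linear phase-position fit within a place field.

    The slope (deg/cm) maximizes the mean resultant length of the
    slope-detrended phases over a candidate grid; the association strength
    is the circular-circular correlation between the phases and the fitted
    line, signed by the slope so that precession (phase advancing as the
    animal moves forward) yields a negative phase-position correlation.
    Requires >= 20 in-field spikes.
    """
    phases = np.asarray(phases, dtype=float)
    positions = np.asarray(positions, dtype=float)
    ok = np.isfinite(phases) & np.isfinite(positions)
    phases, positions = phases[ok], positions[ok]
    if phases.size < min_spikes:
        raise ValueError(f"need at least {min_spikes} spikes, got {phases.size}")
    if np.std(positions) == 0:
        return 0.0, np.nan
    phi = np.deg2rad(phases)
    slopes = np.arange(slope_range[0], slope_range[1] + slope_step / 2, slope_step)
    resultant = np.abs(
        np.mean(np.exp(1j * (phi[None, :] - np.deg2rad(slopes)[:, None] * positions[None, :])),
                axis=1)
    )
    a = float(slopes[int(np.argmax(resultant))])
    theta = np.deg2rad(a * positions)
    # circular-circular correlation (sine-moment form)
    sa_ = np.sin(phi - _circ_mean(phi))
    sb = np.sin(theta - _circ_mean(theta))
    denom = np.sqrt(np.sum(sa_**2) * np.sum(sb**2))
    rho = float(np.sum(sa_ * sb) / denom) if denom > 0 else np.nan
    r = rho if a >= 0 else -rho
    return a, r


def _circ_mean(x: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * x))))


def theta_sequences(
    field_peaks: dict[str, float],
    spike_trains: dict[str, np.ndarray],
    running: IntervalSet,
    max_distance: float = 40.0,
    max_lag: float = 0.125,
    bin_size: float = 0.005,
    min_pairs: int = 5,
) -> tuple[float, float, int]:
    """Field-distance versus theta-lag correlation for one session.

    For place-cell pairs whose field peaks lie within 40 cm, the running
    spike cross-correlogram peak within one theta cycle (+-125 ms) measures
    the within-cycle firing interval; returns the Pearson (r, p) of signed
    field distance against that lag, and the number of pairs used.
    """
    units = sorted(field_peaks)
    dists, lags_peak = [], []
    n_lag = int(round(max_lag / bin_size))
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            a, b = units[i], units[j]
            dist = field_peaks[b] - field_peaks[a]
            if abs(dist) >= max_distance or dist == 0:
                continue
            lag = _xcorr_peak_lag(
                running.restrict(spike_trains[a]),
                running.restrict(spike_trains[b]),
                n_lag,
                bin_size,
            )
            if lag is None:
                continue
            dists.append(dist)
            lags_peak.append(lag)
    if len(dists) < min_pairs:
        return np.nan, np.nan, len(dists)
    r, p = sstats.pearsonr(dists, lags_peak)
    return float(r), float(p), len(dists)


def _xcorr_peak_lag(ta: np.ndarray, tb: np.ndarray, n_lag: int, bin_size: float):
    """Lag (s) of the smoothed spike cross-correlogram peak; positive when
    b tends to fire after a."""
    if ta.size < 5 or tb.size < 5:
        return None
    counts = np.zeros(2 * n_lag + 1)
    lo = np.searchsorted(tb, ta - (n_lag + 0.5) * bin_size)
    hi = np.searchsorted(tb, ta + (n_lag + 0.5) * bin_size)
    for k in range(ta.size):
        if hi[k] > lo[k]:
            d = tb[lo[k] : hi[k]] - ta[k]
            idx = np.round(d / bin_size).astype(int) + n_lag
            np.add.at(counts, np.clip(idx, 0, counts.size - 1), 1)
    if counts.sum() < 10:
        return None
    sm = gaussian_smooth(counts, 2.0)
    return (np.argmax(sm) - n_lag) * bin_size
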