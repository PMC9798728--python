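"""Ground-truth session generator.

Emulates a rat running back and forth along a C-shaped track for food
rewards, with immobility bouts at the reward ends and occasional mid-track
stops.  Spikes are drawn from an inhomogeneous Poisson process whose
intensity is the product of

* a direction-dependent spatial tuning curve (a Gaussian place field per
  running direction, mixed across directions by the directionality factor
  ``d``: ``d = 0`` gives identical curves in both directions, ``d = 1``
  fully independent fields),
* a linear speed gain (Hz per cm/s),
* a theta-phase envelope whose preferred phase advances linearly with
  distance traveled through the field (phase precession),
* a shared slow rate modulation common to CA1 and VC units (the source of
  multi-unit coupling between the two regions during running).

The LFP contains a speed-dependent 6-10 Hz theta component during running;
ripple-band bursts with coincident CA1 population bursts, 6-12 Hz
spike-and-wave trains with synchronized VC bursts, and 20-60 Hz EMG bursts
are injected at known times so detector recall can be measured exactly.

PRE/POST session pairs share unit identities (all unit parameters derive
from the seed alone); POST sessions apply the configured drug effects
multiplicatively to the PRE ground truth.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (
    ContinuousSignal,
    IntervalSet,
    PositionTrace,
    SessionBundle,
    SpikeTrain,
    bandpass,
    gaussian_smooth,
)

__all__ = [
    "PostEffects",
    "SimulationConfig",
    "GroundTruth",
    "simulate_session",
    "simulate_experiment",
    "inject_events",
    "track_polyline",
    "bundle_hash",
]

GRID_DT = 0.001  # spike-intensity resolution, s (piecewise-constant thinning grid)
POS_FS = 33.0  # position sampling rate, Hz
POS_RES = 0.25  # position quantization, cm per pixel
LFP_FS = 2000.0  # LFP/EMG sampling rate, Hz


def track_polyline(track_length: float = 350.0) -> np.ndarray:
    """C-shaped track skeleton: two short arms flanking a long arm.

    Arm lengths are 2:3:2 of the total (100 / 150 / 100 cm for the default
    3.5 m track); reward sites sit at the two free ends (arc length 0 and
    ``track_length``).
    """
    a = track_length * 2.0 / 7.0
    b = track_length * 3.0 / 7.0
    return np.array([[0.0, 0.0], [a, 0.0], [a, b], [0.0, b]])


@dataclass
class PostEffects:
    """Multiplicative drug effects applied to the POST session.

    ``rate_scale`` scales CA1 place-field peaks and baselines; a
    ``directionality_shift`` replaces the CA1 directionality factor;
    ``coactivity_decouple`` breaks the CA1-VC (but not CA1-CA1) coupling of
    ripple-associated population bursts; ``hvs_boost`` multiplies the
    high-voltage-spike rate.
    """

    rate_scale: float = 1.0
    directionality_shift: float | None = None
    coactivity_decouple: bool = False
    hvs_boost: float = 1.0


@dataclass
class SimulationConfig:
    track_length: float = 350.0
    n_ca1_units: int = 40
    n_vc_units: int = 15
    session_duration: float = 1200.0  # s (a 20-min track-running session)
    lap_speed_mean: float = 40.0  # cm/s
    lap_speed_sd: float = 6.0
    end_stop_mean: float = 6.0  # s, mean reward-site immobility bout
    midstop_prob: float = 0.15  # per-lap probability of a mid-track stop
    midstop_mean: float = 3.0  # s
    accel_time: float = 1.0  # s, linear speed ramp at starts and stops
    # place fields
    field_width_range: tuple[float, float] = (7.0, 11.0)  # Gaussian sigma, cm
    field_peak_range: tuple[float, float] = (4.0, 14.0)  # Hz
    directionality: float = 1.0  # d in [0, 1]; 0 = identical curves both ways
    baseline_rate: float = 0.1  # Hz, running baseline outside the field
    immobile_rate: float = 0.25  # Hz, CA1 rate during immobility
    speed_gain: float = 0.02  # Hz per cm/s, linear rate-speed modulation
    # shared slow modulation (drives CA1-VC MUA coupling during running)
    shared_mod_depth: float = 0.35
    shared_mod_tau: float = 0.2  # s, smoothing sigma of the modulation
    # VC units: broad, weak spatial modulation, no directionality
    vc_base_range: tuple[float, float] = (2.0, 8.0)  # Hz
    vc_tuning_width: float = 60.0  # cm
    vc_tuning_depth: float = 0.5
    # theta
    theta_freq: float = 8.0  # Hz at the mean lap speed
    theta_speed_slope: float = 0.02  # Hz per cm/s
    theta_mod_depth: float = 0.5  # spike-rate theta envelope depth
    precession_slope: float = -6.0  # deg per cm traveled through the field
    theta_amp: float = 40.0  # uV LFP theta amplitude during running
    # events
    ripple_rate: float = 10.0  # per min of immobility
    hvs_rate: float = 0.2  # per min of immobility
    eht_rate: float = 0.2  # per min of session
    ripple_amp_sd: float = 10.0  # amplitude in baseline-SD units
    ripple_duration: float = 0.08  # s
    ripple_spike_gain: float = 80.0  # Hz peak per-unit burst intensity
    hvs_amp_sd: float = 10.0
    hvs_n_cycles: int = 8
    hvs_cycle_freq: float = 8.0  # Hz
    hvs_spike_gain: float = 40.0  # Hz per VC unit at each trough
    eht_amp_sd: float = 12.0
    eht_duration: float = 0.25  # s
    lfp_noise_sd: float = 15.0  # uV
    emg_noise_sd: float = 10.0  # uV
    post_effects: PostEffects = field(default_factory=PostEffects)
    rng_seed: int = 0

    def validate(self) -> None:
        num = {
            k: v
            for k, v in asdict(self).items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        for k, v in num.items():
            if not np.isfinite(v):
                raise ValueError(f"config field {k} is not finite: {v}")
        for k in ("ripple_rate", "hvs_rate", "eht_rate", "baseline_rate", "immobile_rate"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")
        if not 0.0 <= self.directionality <= 1.0:
            raise ValueError("directionality must lie in [0, 1]")
        if not 0.0 < self.post_effects.rate_scale <= 1.0:
            raise ValueError("post_effects.rate_scale must lie in (0, 1]")
        if self.post_effects.directionality_shift is not None and not (
            0.0 <= self.post_effects.directionality_shift <= 1.0
        ):
            raise ValueError("directionality_shift must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the downstream metrics should recover."""

    ca1_center_traj1: np.ndarray = None
    ca1_center_traj2: np.ndarray = None
    ca1_width: np.ndarray = None
    ca1_peak: np.ndarray = None
    directionality: float = 1.0
    vc_base: np.ndarray = None
    vc_center: np.ndarray = None
    speed_gain: float = 0.0
    baseline_rate: float = 0.0
    theta_freq: float = 8.0
    precession_slope: float = 0.0
    mean_speed: float = np.nan  # full-session time-average of |v|
    mean_running_speed: float = np.nan  # time-average of |v| while > 10 cm/s
    #: generative |v| sampled at the position timestamps
    speed_at_pos: np.ndarray = field(default_factory=lambda: np.empty(0))
    laps: list = field(default_factory=list)  # (start, end, direction)
    immobility: list = field(default_factory=list)  # (start, end)
    ripple_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    ripple_content: np.ndarray = field(default_factory=lambda: np.empty(0))
    hvs_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    eht_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: per-unit time-integral of the generative intensity (expected spike
    #: count, excluding injected event bursts)
    expected_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return json.dumps({k: conv(v) for k, v in self.__dict__.items()}, sort_keys=True)


# ---------------------------------------------------------------------------
# unit parameter draws (shared between PRE and POST of one experiment)


def _unit_params(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    T = cfg.track_length
    margin = 20.0
    n = cfg.n_ca1_units
    p = {
        "c1": rng.uniform(margin, T - margin, n),
        "c2": rng.uniform(margin, T - margin, n),
        "width": rng.uniform(*cfg.field_width_range, n),
        "peak": rng.uniform(*cfg.field_peak_range, n),
        "phi0": rng.uniform(0, 360.0, n),
        "vc_base": rng.uniform(*cfg.vc_base_range, cfg.n_vc_units),
        # centers kept away from the ends: the broad VC modulation should
        # not lose kernel mass off the track (edge units would otherwise
        # carry a systematically weaker drive in every context)
        "vc_center": rng.uniform(cfg.vc_tuning_width, T - cfg.vc_tuning_width, cfg.n_vc_units),
    }
    return p


# ---------------------------------------------------------------------------
# behavior synthesis


def _synthesize_behavior(cfg: SimulationConfig, rng: np.random.Generator):
    """Piecewise-constant 1-D trajectory on the millisecond grid.

    Returns (pos, vel_signed, laps, immobility) where laps is a list of
    (start, end, direction) and immobility a list of (start, end).
    """
    T = cfg.track_length
    n_grid = int(round(cfg.session_duration / GRID_DT))
    pos = np.empty(n_grid)
    vel = np.zeros(n_grid)
    laps: list[tuple[float, float, int]] = []
    immobility: list[tuple[float, float]] = []

    i = 0
    x = 0.0
    direction = 1
    while i < n_grid:
        # reward-site immobility bout
        bout = max(2.0, rng.gamma(2.0, cfg.end_stop_mean / 2.0))
        n_b = min(n_grid - i, int(round(bout / GRID_DT)))
        pos[i : i + n_b] = x
        immobility.append((i * GRID_DT, (i + n_b) * GRID_DT))
        i += n_b
        if i >= n_grid:
            break
        # traversal, possibly with one mid-track stop; each leg follows a
        # trapezoidal speed profile (linear accelerate / cruise / decelerate)
        v = float(np.clip(rng.normal(cfg.lap_speed_mean, cfg.lap_speed_sd), 12.0, None))
        target = T if direction == 1 else 0.0
        legs: list[tuple[float, float]] = [(x, target)]
        stop_dur = 0.0
        if rng.random() < cfg.midstop_prob:
            stop_at = rng.uniform(0.25 * T, 0.75 * T)
            stop_dur = max(1.5, rng.exponential(cfg.midstop_mean))
            legs = [(x, stop_at), (stop_at, target)]
        lap_start = i * GRID_DT
        truncated = False
        for li, (x0, x1) in enumerate(legs):
            dist = abs(x1 - x0)
            n_r = max(1, int(round(cfg.accel_time / GRID_DT)))
            if dist >= v * cfg.accel_time:
                n_c = int(round((dist - v * cfg.accel_time) / v / GRID_DT))
                prof = np.concatenate([
                    np.linspace(0.0, v, n_r, endpoint=False),
                    np.full(n_c, v),
                    np.linspace(v, 0.0, n_r, endpoint=False),
                ])
            else:
                vp = dist / cfg.accel_time
                prof = np.concatenate([
                    np.linspace(0.0, vp, n_r, endpoint=False),
                    np.linspace(vp, 0.0, n_r, endpoint=False),
                ])
            cum = np.cumsum(prof) * GRID_DT
            if cum[-1] > 0:
                leg_pos = x0 + (x1 - x0) * cum / cum[-1]
            else:
                leg_pos = np.full(prof.size, x0)
            n_leg = prof.size
            if n_leg > n_grid - i:
                n_done = n_grid - i
                pos[i:n_grid] = leg_pos[:n_done]
                vel[i:n_grid] = direction * prof[:n_done]
                i = n_grid
                truncated = True
                break
            pos[i : i + n_leg] = leg_pos
            vel[i : i + n_leg] = direction * prof
            i += n_leg
            x = x1
            if li == 0 and len(legs) == 2:
                n_s = min(n_grid - i, int(round(stop_dur / GRID_DT)))
                pos[i : i + n_s] = x
                immobility.append((i * GRID_DT, (i + n_s) * GRID_DT))
                i += n_s
                if i >= n_grid:
                    truncated = True
                    break
        if not truncated and abs(x - target) < 1e-9:
            laps.append((lap_start, i * GRID_DT, direction))
            direction = -direction
    return pos, vel, laps, immobility


def _arc_to_xy(arc: np.ndarray, poly: np.ndarray) -> np.ndarray:
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    arc = np.clip(arc, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(seg_len) - 1)
    frac = (arc - cum[idx]) / seg_len[idx]
    return poly[idx] + frac[:, None] * seg[idx]


# ---------------------------------------------------------------------------
# spike sampling


def _sample_inhomogeneous(lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact draw from a piecewise-constant-intensity Poisson process.

    Per-bin Poisson counts with uniform placement inside the bin -- exact
    for an intensity constant within each 1 ms bin.
    """
    counts = rng.poisson(lam * GRID_DT)
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        return np.empty(0)
    reps = counts[nz]
    lefts = np.repeat(nz.astype(float) * GRID_DT, reps)
    return np.sort(lefts + rng.random(lefts.size) * GRID_DT)


def _ca1_intensity(
    cfg, p, i, pos, vel, running, theta_phase, shared_mod, d, rate_scale
):
    """Generative intensity of CA1 unit ``i`` on the millisecond grid."""
    w = p["width"][i]
    g1 = np.exp(-0.5 * ((pos - p["c1"][i]) / w) ** 2)
    g2 = np.exp(-0.5 * ((pos - p["c2"][i]) / w) ** 2)
    fwd = vel > 0
    spatial = np.where(fwd, g1, d * g2 + (1.0 - d) * g1) * p["peak"][i]
    lam = spatial + cfg.baseline_rate + cfg.speed_gain * np.abs(vel)
    # theta envelope with phase precession: preferred phase advances with
    # distance traveled through the active-direction field
    c_dir = np.where(fwd, p["c1"][i], p["c2"][i] if d > 0 else p["c1"][i])
    traveled = np.sign(vel) * (pos - c_dir)
    phi_pref = np.deg2rad(p["phi0"][i] + cfg.precession_slope * traveled)
    env = 1.0 + cfg.theta_mod_depth * np.cos(theta_phase - phi_pref)
    lam = lam * np.where(running, env * shared_mod, 0.0)
    lam += np.where(running, 0.0, cfg.immobile_rate)
    # the drug effect is a global multiplicative rate reduction
    return lam * rate_scale


def _vc_intensity(cfg, p, j, pos, running, shared_mod):
    base = p["vc_base"][j]
    tune = 1.0 + cfg.vc_tuning_depth * np.exp(
        -0.5 * ((pos - p["vc_center"][j]) / cfg.vc_tuning_width) ** 2
    )
    lam = np.where(running, base * tune * shared_mod, 0.5 * base)
    return lam


# ---------------------------------------------------------------------------
# event injection


def _filtered_sd(sig: ContinuousSignal, lo: float, hi: float) -> float:
    return float(np.std(bandpass(sig.samples, sig.sampling_rate, lo, hi)))


def inject_events(
    bundle: SessionBundle,
    truth: GroundTruth,
    kind: str,
    times: np.ndarray | None = None,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SessionBundle:
    """Add ripple / HVS / eHT waveforms (and associated spike bursts) at
    the given times; times are recorded in ``truth``.

    ``times`` defaults to the corresponding ``truth`` field.  The returned
    bundle is a copy; the input bundle is untouched.
    """
    cfg = cfg or SimulationConfig(track_length=bundle.metadata.get("track_length", 350.0))
    rng = rng or np.random.default_rng(12345)
    if kind not in ("ripple", "hvs", "eht"):
        raise ValueError(f"unknown event kind: {kind}")
    if times is None:
        times = getattr(truth, f"{kind}_times")
    times = np.sort(np.asarray(times, dtype=float))
    dur = bundle.duration
    if times.size and (times.min() < 0 or times.max() > dur):
        raise ValueError("event time outside the session range")

    out = copy.deepcopy(bundle)
    if times.size == 0:
        out.metadata.setdefault("injected", {})[kind] = 0
        return out

    if kind == "ripple":
        sig = out.lfp["CA1"]
        sd = _filtered_sd(sig, 100.0, 250.0)
        n_env = int(round(cfg.ripple_duration * sig.sampling_rate))
        tt = np.arange(n_env) / sig.sampling_rate - cfg.ripple_duration / 2.0
        # spindle-shaped Gaussian envelope: the center trough clearly
        # dominates its neighbors, pinning the detector's peak time
        env = np.exp(-0.5 * (tt / (cfg.ripple_duration / 6.0)) ** 2)
        # -cos carrier: the deepest trough of the injected burst sits at the
        # injection time, matching the detector's peak-time definition
        wave = -cfg.ripple_amp_sd * sd * env * np.cos(2 * np.pi * 175.0 * tt)
        content = getattr(truth, "ripple_content", np.empty(0))
        if content is None or len(content) != times.size:
            content = rng.uniform(0.0, cfg.track_length, times.size)
        spikes_extra = _ripple_bursts(out, cfg, times, content, rng)
        for t in times:
            i0 = sig.index_of(t) - n_env // 2
            i0 = int(np.clip(i0, 0, sig.samples.size - n_env))
            sig.samples[i0 : i0 + n_env] += wave
        _merge_spikes(out, spikes_extra)
        truth.ripple_times = times
        truth.ripple_content = np.asarray(content)
    elif kind == "hvs":
        sig = out.lfp["VC"]
        sd = _filtered_sd(sig, 6.0, 12.0)
        ev_dur = cfg.hvs_n_cycles / cfg.hvs_cycle_freq
        n_env = int(round(ev_dur * sig.sampling_rate))
        from scipy.signal.windows import tukey

        env = tukey(n_env, alpha=0.25)
        tt = np.arange(n_env) / sig.sampling_rate
        wave = -cfg.hvs_amp_sd * sd * env * np.cos(2 * np.pi * cfg.hvs_cycle_freq * tt)
        trough_offsets = (np.arange(cfg.hvs_n_cycles)) / cfg.hvs_cycle_freq
        spikes_extra = {}
        for t in times:
            i0 = sig.index_of(t)
            i0 = int(np.clip(i0, 0, sig.samples.size - n_env))
            sig.samples[i0 : i0 + n_env] += wave
            # synchronized VC bursts at every spike-and-wave trough
            for st in out.spikes_by_region("VC"):
                lam_peak = cfg.hvs_spike_gain
                for off in trough_offsets:
                    n_sp = rng.poisson(lam_peak * 0.03)
                    if n_sp:
                        ts = t + off + rng.normal(0.0, 0.012, n_sp)
                        spikes_extra.setdefault(st.unit_id, []).append(ts)
        _merge_spikes(out, spikes_extra)
        truth.hvs_times = times
    else:  # eht
        sig = out.emg
        sd = _filtered_sd(sig, 20.0, 60.0)
        n_env = int(round(cfg.eht_duration * sig.sampling_rate))
        # a head twitch is a train of >= 2 distinct EMG deflections; two
        # sub-bursts whose peaks sit > 0.1 s apart within the event
        env = np.zeros(n_env)
        nb = int(0.4 * n_env)
        env[:nb] = np.hanning(nb)
        env[n_env - nb:] = np.maximum(env[n_env - nb:], np.hanning(nb))
        tt = np.arange(n_env) / sig.sampling_rate
        wave = cfg.eht_amp_sd * sd * env * np.sin(2 * np.pi * 40.0 * tt)
        for t in times:
            i0 = sig.index_of(t)
            i0 = int(np.clip(i0, 0, sig.samples.size - n_env))
            sig.samples[i0 : i0 + n_env] += wave
        truth.eht_times = times
    out.metadata.setdefault("injected", {})[kind] = int(times.size)
    return out


def _ripple_bursts(bundle, cfg, times, content, rng):
    """CA1 population bursts coincident with each ripple; burst weight of a
    unit is its trajectory-1 tuning evaluated at the ripple's replay
    location, so pairs with overlapping fields co-fire within ripples."""
    p = bundle.metadata.get("unit_params")
    spikes_extra: dict[str, list] = {}
    half = cfg.ripple_duration / 2.0
    for st in bundle.spikes_by_region("CA1"):
        i = int(st.unit_id.split("_")[-1])
        if p is not None:
            # participation kernel is broader than a place field (a ripple
            # recruits cells around the replayed location, not only at it),
            # engages either direction's field, and keeps a small
            # location-independent baseline participation; its breadth is a
            # fixed property of the ripple, not of the unit's field width,
            # so ripple participation carries no unit-level gain shared
            # with the running-coactivity sensitivity
            sig = 20.0
            k1 = np.exp(-0.5 * ((np.asarray(content) - p["c1"][i]) / sig) ** 2)
            k2 = np.exp(-0.5 * ((np.asarray(content) - p["c2"][i]) / sig) ** 2)
            w = 0.15 + 0.85 * np.maximum(k1, k2)
            # replay order: a unit's burst leads/lags the ripple center in
            # proportion to its field's (time-compressed) distance from the
            # replayed location, so nearby-field pairs co-fire at short lags
            near_c = np.where(k1 >= k2, p["c1"][i], p["c2"][i])
            burst_dt = np.clip(0.0006 * (near_c - np.asarray(content)), -0.03, 0.03)
        else:
            w = rng.random(len(times))
            burst_dt = np.zeros(len(times))
        lam = cfg.ripple_spike_gain * w
        for t, l, bdt in zip(times, lam, burst_dt):
            n_sp = rng.poisson(l * cfg.ripple_duration * 0.5)  # hanning mean ~0.5
            if n_sp:
                ts = t + bdt + rng.normal(0.0, 0.008, n_sp)
                ts = np.clip(ts, t - half, t + half)
                spikes_extra.setdefault(st.unit_id, []).append(ts)
    # VC units respond around ripples according to their tuning at the
    # (possibly decoupled) replay location
    decouple = bundle.metadata.get("coactivity_decouple", False)
    vc_content = (
        rng.uniform(0.0, cfg.track_length, len(times)) if decouple else np.asarray(content)
    )
    for st in bundle.spikes_by_region("VC"):
        j = int(st.unit_id.split("_")[-1])
        if p is not None:
            w = np.exp(
                -0.5 * ((vc_content - p["vc_center"][j]) / (cfg.vc_tuning_width / 2.0)) ** 2
            )
            # response gain scales with sqrt(baseline): the shuffle-Z of a
            # burst against a Poisson background grows as burst/sqrt(bg),
            # so this keeps ripple-response Z homogeneous across units and
            # avoids a unit-level gain common to running and ripple
            # coactivity (which would correlate even when decoupled)
            w = w * np.sqrt(p["vc_base"][j] / np.mean(cfg.vc_base_range))
        else:
            w = rng.random(len(times))
        lam = 0.5 * cfg.ripple_spike_gain * w
        for t, l in zip(times, lam):
            n_sp = rng.poisson(l * 0.1 * 0.5)
            if n_sp:
                ts = t + rng.normal(0.0, 0.05, n_sp)
                spikes_extra.setdefault(st.unit_id, []).append(ts)
    return spikes_extra


def _merge_spikes(bundle: SessionBundle, extra: dict[str, list]) -> None:
    for st in bundle.spikes:
        if st.unit_id in extra:
            add = np.concatenate(extra[st.unit_id])
            add = add[(add >= 0) & (add <= bundle.duration)]
            st.times = np.sort(np.concatenate([st.times, add]))


def _draw_event_times(
    rate_per_min: float,
    intervals: list[tuple[float, float]],
    rng: np.random.Generator,
    min_sep: float,
    margin: float,
    min_len: float = 0.0,
) -> np.ndarray:
    """Poisson event times confined to the given intervals (with margins)."""
    usable = [
        (s + margin, e - margin)
        for s, e in intervals
        if (e - s) >= max(min_len, 2 * margin + 0.05)
    ]
    if not usable:
        return np.empty(0)
    total = sum(e - s for s, e in usable)
    n = rng.poisson(rate_per_min * total / 60.0)
    if n == 0:
        return np.empty(0)
    edges = np.cumsum([0.0] + [e - s for s, e in usable])
    u = np.sort(rng.uniform(0.0, total, n))
    idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, len(usable) - 1)
    times = np.array([usable[i][0] + (x - edges[i]) for i, x in zip(idx, u)])
    # enforce a minimum separation by greedy thinning
    keep, last = [], -np.inf
    for t in times:
        if t - last >= min_sep:
            keep.append(t)
            last = t
    return np.asarray(keep)


# ---------------------------------------------------------------------------
# main entry points


def simulate_session(
    config: SimulationConfig, session_label: str = "PRE"
) -> tuple[SessionBundle, GroundTruth]:
    """Generate one session.  ``session_label`` must be ``PRE`` or ``POST``;
    POST applies ``config.post_effects``.  Unit parameters depend only on
    the seed, so PRE and POST of the same config share unit identities."""
    config.validate()
    if session_label not in ("PRE", "POST"):
        raise ValueError("session_label must be PRE or POST")
    ss = np.random.SeedSequence(config.rng_seed)
    kids = ss.spawn(6)
    rng_units = np.random.default_rng(kids[0])
    sidx = 0 if session_label == "PRE" else 1
    rng_behav = np.random.default_rng(kids[1 + sidx])
    rng_spk = np.random.default_rng(kids[3 + sidx])
    rng_ev = np.random.default_rng(kids[5].spawn(2)[sidx])

    p = _unit_params(config, rng_units)
    eff = config.post_effects if session_label == "POST" else PostEffects()
    d = config.directionality
    if session_label == "POST" and eff.directionality_shift is not None:
        d = eff.directionality_shift

    pos, vel, laps, immobility = _synthesize_behavior(config, rng_behav)
    n_grid = pos.size
    grid_t = np.arange(n_grid) * GRID_DT
    running = np.abs(vel) > 1e-9
    speed = np.abs(vel)

    # theta phase advances at a speed-dependent frequency during running
    f_inst = np.where(
        running,
        np.clip(
            config.theta_freq
            + config.theta_speed_slope * (speed - config.lap_speed_mean),
            6.0,
            10.0,
        ),
        config.theta_freq,
    )
    theta_phase = 2 * np.pi * np.cumsum(f_inst) * GRID_DT

    # shared slow modulation (CA1-VC coupling source)
    z = rng_spk.standard_normal(n_grid // 100 + 2)
    z = gaussian_smooth(z, config.shared_mod_tau / (GRID_DT * 100))
    z = np.interp(grid_t, np.arange(z.size) * GRID_DT * 100, z)
    z /= max(np.std(z), 1e-12)
    # the drug effect scales the shared modulation along with the rates, so
    # CA1-VC co-fluctuations (hence MUA coupling) weaken in POST
    mod_depth = config.shared_mod_depth * eff.rate_scale
    shared_mod = np.clip(1.0 + mod_depth * z, 0.05, None)

    spikes: list[SpikeTrain] = []
    expected_counts: dict[str, float] = {}
    for i in range(config.n_ca1_units):
        lam = _ca1_intensity(
            config, p, i, pos, vel, running, theta_phase, shared_mod, d, eff.rate_scale
        )
        expected_counts[f"ca1_{i}"] = float(np.sum(lam) * GRID_DT)
        spikes.append(SpikeTrain(f"ca1_{i}", "CA1", _sample_inhomogeneous(lam, rng_spk)))
    for j in range(config.n_vc_units):
        lam = _vc_intensity(config, p, j, pos, running, shared_mod)
        expected_counts[f"vc_{j}"] = float(np.sum(lam) * GRID_DT)
        spikes.append(SpikeTrain(f"vc_{j}", "VC", _sample_inhomogeneous(lam, rng_spk)))

    # position trace at 33 Hz with tracking noise and pixel quantization
    poly = track_polyline(config.track_length)
    t_pos = np.arange(0.0, config.session_duration - 0.5 / POS_FS, 1.0 / POS_FS)
    arc = np.interp(t_pos, grid_t, pos)
    xy = _arc_to_xy(arc, poly)
    xy = xy + rng_behav.normal(0.0, POS_RES, xy.shape)  # ~1 pixel jitter
    xy = np.round(xy / POS_RES) * POS_RES
    positions = PositionTrace(t_pos, xy[:, 0], xy[:, 1])

    # LFP: broadband noise + theta during running (smoothly gated)
    n_lfp = int(round(config.session_duration * LFP_FS))
    t_lfp = np.arange(n_lfp) / LFP_FS
    run_gate = gaussian_smooth(
        np.interp(t_lfp, grid_t, running.astype(float)), 0.2 * LFP_FS
    )
    theta_lfp = np.interp(t_lfp, grid_t, np.cos(theta_phase))
    lfp_ca1 = rng_spk.normal(0.0, config.lfp_noise_sd, n_lfp)
    lfp_ca1 += config.theta_amp * run_gate * theta_lfp
    lfp_vc = rng_spk.normal(0.0, config.lfp_noise_sd, n_lfp)
    lfp_vc += 0.5 * config.theta_amp * run_gate * theta_lfp
    emg = rng_spk.normal(0.0, config.emg_noise_sd, n_lfp)

    bundle = SessionBundle(
        positions=positions,
        spikes=spikes,
        lfp={
            "CA1": ContinuousSignal("CA1", LFP_FS, lfp_ca1),
            "VC": ContinuousSignal("VC", LFP_FS, lfp_vc),
        },
        emg=ContinuousSignal("EMG", LFP_FS, emg),
        metadata={
            "session_label": session_label,
            "session_duration": config.session_duration,
            "track_length": config.track_length,
            "reward_sites": [0.0, config.track_length],
            "track_polyline": poly.tolist(),
            "rng_seed": config.rng_seed,
            "unit_params": p,
            "coactivity_decouple": bool(
                session_label == "POST" and eff.coactivity_decouple
            ),
        },
    )

    truth = GroundTruth(
        ca1_center_traj1=p["c1"].copy(),
        ca1_center_traj2=np.where(d > 0, p["c2"], p["c1"]).copy(),
        ca1_width=p["width"].copy(),
        ca1_peak=p["peak"] * eff.rate_scale,
        directionality=d,
        vc_base=p["vc_base"].copy(),
        vc_center=p["vc_center"].copy(),
        speed_gain=config.speed_gain,
        baseline_rate=config.baseline_rate * eff.rate_scale,
        theta_freq=config.theta_freq,
        precession_slope=config.precession_slope,
        mean_speed=float(np.mean(speed)),
        mean_running_speed=float(np.mean(speed[speed > 10.0])) if np.any(speed > 10.0) else np.nan,
        speed_at_pos=np.interp(t_pos, grid_t, speed),
        laps=laps,
        immobility=immobility,
        expected_counts=expected_counts,
    )

    # events
    ripple_times = _draw_event_times(
        config.ripple_rate, immobility, rng_ev, min_sep=0.6, margin=0.3
    )
    hvs_rate = config.hvs_rate * (eff.hvs_boost if session_label == "POST" else 1.0)
    hvs_len = config.hvs_n_cycles / config.hvs_cycle_freq
    hvs_times = _draw_event_times(
        hvs_rate, immobility, rng_ev, min_sep=hvs_len + 1.0, margin=0.3, min_len=hvs_len + 0.8
    )
    run_iv = [(s, e) for s, e, _ in laps]
    eht_times = _draw_event_times(
        config.eht_rate, run_iv, rng_ev, min_sep=1.0, margin=0.4
    )
    truth.ripple_content = rng_ev.uniform(0.0, config.track_length, ripple_times.size)
    bundle = inject_events(bundle, truth, "ripple", ripple_times, config, rng_ev)
    bundle = inject_events(bundle, truth, "hvs", hvs_times, config, rng_ev)
    bundle = inject_events(bundle, truth, "eht", eht_times, config, rng_ev)
    return bundle, truth


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[SessionBundle, SessionBundle, GroundTruth, GroundTruth]:
    """One PRE/POST pair sharing unit identities."""
    pre, truth_pre = simulate_session(config, "PRE")
    post, truth_post = simulate_session(config, "POST")
    return pre, post, truth_pre, truth_post


def bundle_hash(bundle: SessionBundle) -> str:
    """SHA256 over every array in the bundle (byte-identity check)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(bundle.positions.t).tobytes())
    h.update(np.ascontiguousarray(bundle.positions.x).tobytes())
    h.update(np.ascontiguousarray(bundle.positions.y).tobytes())
    for st in sorted(bundle.spikes, key=lambda s: s.unit_id):
        h.update(st.unit_id.encode())
        h.update(np.ascontiguousarray(st.times).tobytes())
    for key in sorted(bundle.lfp):
        h.update(np.ascontiguousarray(bundle.lfp[key].samples).tobytes())
    h.update(np.ascontiguousarray(bundle.emg.samples).tobytes())
    return h.hexdigest()
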