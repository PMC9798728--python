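"""End-to-end orchestration: simulate (or load) a PRE/POST session pair,
run behavior -> spatial -> population -> events -> theta -> pairwise ->
stats, and emit a JSON-serializable report comparing PRE and POST.

The immobility speed threshold is estimated in PRE and reused for POST
(same threshold per animal); immobility-dependent POST metrics (HVS
occupancy, ripple rate) are restricted to the first 30 minutes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import events as ev
from . import pairwise as pw
from . import population as pop
from . import spatial as sp
from . import stats as st
from .core import IntervalSet, SessionBundle
from .synthetic import SimulationConfig, simulate_session

__all__ = ["SessionAnalysis", "analyze_session", "run_experiment", "report_hash"]

POST_IMMOBILITY_WINDOW_MIN = 30.0
ALPHA = 0.05


@dataclass
class SessionAnalysis:
    bundle: SessionBundle
    lin: object
    speed: object
    laps: IntervalSet
    stops: IntervalSet
    immobility: IntervalSet
    immobility_threshold: float
    running: IntervalSet
    eht: IntervalSet
    ripples: IntervalSet
    hvs: IntervalSet
    curves: dict = field(default_factory=dict)  # (unit_id, traj) -> RateCurve
    rates: pd.DataFrame | None = None  # unit_id, region, trajectory, rate, n_spikes
    summary: dict = field(default_factory=dict)


def analyze_session(
    bundle: SessionBundle, immobility_threshold: float | None = None
) -> SessionAnalysis:
    """Behavioral segmentation, event detection, and per-unit rate curves
    for one session."""
    meta = bundle.metadata
    poly = np.asarray(meta["track_polyline"])
    reward_sites = meta.get("reward_sites", [0.0, meta.get("track_length", 350.0)])
    speed = bhv.compute_speed(bundle.positions)
    lin = bhv.linearize(bundle.positions, poly)
    immobility, thr = bhv.detect_immobility(
        speed, lin, reward_sites, threshold=immobility_threshold
    )
    stops = bhv.detect_stops(speed)
    laps = bhv.segment_laps(lin)
    dur = bundle.duration
    running = immobility.complement(0.0, dur, "running").intersect(laps, "running") \
        if len(laps) else IntervalSet("running")
    eht = bhv.detect_eht(bundle.emg)
    ripples = ev.detect_ripples(bundle.lfp["CA1"])
    hvs = ev.detect_hvs(bundle.lfp["VC"])

    curves, rate_rows = {}, []
    for st_ in bundle.spikes:
        for traj in (1, -1):
            r = sp.running_rate(st_, laps, stops, traj)
            n_spk = sp._spikes_in_laps(st_, laps, stops, traj).size
            rate_rows.append((st_.unit_id, st_.region, traj, r, n_spk))
            if st_.region == "CA1":
                curves[(st_.unit_id, traj)] = sp.compute_rate_curve(
                    st_, lin, laps, stops, traj,
                    track_length=meta.get("track_length"),
                    reward_sites=reward_sites,
                )
    rates = pd.DataFrame(
        rate_rows, columns=["unit_id", "region", "trajectory", "rate", "n_spikes"]
    )
    sa = SessionAnalysis(
        bundle, lin, speed, laps, stops, immobility, thr, running, eht,
        ripples, hvs, curves, rates,
    )
    sa.summary = bhv.behavior_summary(laps, speed, immobility, eht, dur)
    return sa


def _spatial_metrics(pre: SessionAnalysis, post: SessionAnalysis) -> dict:
    """Per-unit SI, stability, directionality, fields, within-field rates."""
    out = {"si": {}, "stability": {}, "directionality": {"PRE": {}, "POST": {}},
           "fields": {"PRE": [], "POST": []},
           "within_field_rate": {"PRE": [], "POST": []},
           "field_length": {"PRE": [], "POST": []}}
    sessions = {"PRE": pre, "POST": post}

    def rate_of(sa, unit, traj):
        df = sa.rates
        row = df[(df.unit_id == unit) & (df.trajectory == traj)]
        return (row.rate.iloc[0], row.n_spikes.iloc[0]) if len(row) else (np.nan, 0)

    ca1_units = sorted({u for (u, _) in pre.curves})
    for unit in ca1_units:
        for traj in (1, -1):
            for label, sa in sessions.items():
                r, _ = rate_of(sa, unit, traj)
                if np.isfinite(r) and r > sp.ACTIVE_RATE:
                    out["si"][(unit, traj, label)] = sp.spatial_information(
                        sa.curves[(unit, traj)]
                    )
                    flds = sp.detect_place_fields(sa.curves[(unit, traj)])
                    for f in flds:
                        out["fields"][label].append((unit, f))
                        out["within_field_rate"][label].append(f.within_field_rate)
                        out["field_length"][label].append(f.length)
            # stability: active in one session, >= 1 spike in the other
            r_pre, n_pre = rate_of(pre, unit, traj)
            r_post, n_post = rate_of(post, unit, traj)
            if ((r_pre > sp.ACTIVE_RATE and n_post >= 1)
                    or (r_post > sp.ACTIVE_RATE and n_pre >= 1)):
                out["stability"][(unit, traj)] = sp.stability(
                    pre.curves[(unit, traj)], post.curves[(unit, traj)]
                )
        # directionality per session: active on one trajectory, spike on other
        for label, sa in sessions.items():
            r1, n1 = rate_of(sa, unit, 1)
            r2, n2 = rate_of(sa, unit, -1)
            if (r1 > sp.ACTIVE_RATE and n2 >= 1) or (r2 > sp.ACTIVE_RATE and n1 >= 1):
                out["directionality"][label][unit] = sp.directionality(
                    sa.curves[(unit, 1)], sa.curves[(unit, -1)]
                )
    return out


def _pv_metrics(pre: SessionAnalysis, post: SessionAnalysis) -> dict:
    out = {}
    sessions = {"PRE": pre, "POST": post}
    pvs = {}
    for label, sa in sessions.items():
        for traj in (1, -1):
            active_any = set()
            for other in sessions.values():
                df = other.rates
                act = df[(df.trajectory == traj) & (df.region == "CA1")
                         & (df.rate > sp.ACTIVE_RATE)]
                active_any |= set(act.unit_id)
            curves = {u: sa.curves[(u, traj)] for u in active_any if (u, traj) in sa.curves}
            if len(curves) >= pop.MIN_ACTIVE_UNITS:
                pvs[(label, traj)] = pop.build_pv(curves, traj, label)
    cross_session = []
    for traj in (1, -1):
        if ("PRE", traj) in pvs and ("POST", traj) in pvs:
            _, m = pop.pv_correlation(pvs[("PRE", traj)], pvs[("POST", traj)])
            cross_session.append(m)
    out["cross_session_mean"] = float(np.nanmean(cross_session)) if cross_session else np.nan
    for label in ("PRE", "POST"):
        if (label, 1) in pvs and (label, -1) in pvs:
            a, b = pvs[(label, 1)], pvs[(label, -1)]
            if a.unit_ids != b.unit_ids:
                common = sorted(set(a.unit_ids) & set(b.unit_ids))
                if len(common) < pop.MIN_ACTIVE_UNITS:
                    out[f"cross_trajectory_{label}"] = np.nan
                    continue
                ia = [a.unit_ids.index(u) for u in common]
                ib = [b.unit_ids.index(u) for u in common]
                for m_, idx in ((a, ia), (b, ib)):
                    m_.matrix = m_.matrix[:, idx]
                    m_.unit_ids = common
                    act = np.nan_to_num(m_.matrix) > pop.BIN_ACTIVE_RATE
                    m_.active_count = act.sum(axis=1)
                    m_.eligible = (m_.active_count >= pop.MIN_ACTIVE_UNITS) & np.all(
                        np.isfinite(m_.matrix), axis=1)
            _, m = pop.pv_correlation(a, b)
            out[f"cross_trajectory_{label}"] = m
        else:
            out[f"cross_trajectory_{label}"] = np.nan
    return out


def _mua_metrics(sa: SessionAnalysis) -> dict:
    dur = sa.bundle.duration
    t, mua_ca1 = pw.mua_trace([s.times for s in sa.bundle.spikes_by_region("CA1")], 0, dur)
    _, mua_vc = pw.mua_trace([s.times for s in sa.bundle.spikes_by_region("VC")], 0, dur)
    xc = pw.mua_xcorr(t, mua_ca1, mua_vc, sa.running)
    peak_val, peak_lag = xc.peak
    return {"peak": peak_val, "peak_lag": peak_lag, "n_periods": xc.n_events}


def _pairwise_metrics(sa: SessionAnalysis, rng: np.random.Generator,
                      n_shuffles: int = pw.N_SHUFFLES) -> dict:
    """Coactivity during running and within/around ripples; reactivation."""
    df = sa.rates
    run_rate = {r.unit_id: max(
        df[(df.unit_id == r.unit_id)].rate.max(), 0.0) for r in df.itertuples()}
    spk = {s.unit_id: s for s in sa.bundle.spikes}
    ca1 = sorted(s.unit_id for s in sa.bundle.spikes_by_region("CA1"))
    vc = sorted(s.unit_id for s in sa.bundle.spikes_by_region("VC"))

    def n_run_spikes(u):
        return sa.running.restrict(spk[u].times).size

    def eligible(u, v):
        return ((run_rate[u] > sp.ACTIVE_RATE and n_run_spikes(v) >= 1)
                or (run_rate[v] > sp.ACTIVE_RATE and n_run_spikes(u) >= 1))

    rip_win = pw.ripple_windows(sa.ripples)
    res = {"ca1_pairs": [], "ca1vc_pairs": []}
    for i in range(len(ca1)):
        for j in range(i + 1, len(ca1)):
            u, v = ca1[i], ca1[j]
            if not eligible(u, v):
                continue
            c_run = pw.coactivity(pw.normalized_xcorr(
                spk[u].times, spk[v].times, sa.running, "running",
                n_shuffles=n_shuffles, rng=rng))
            c_rip = np.nan
            if len(sa.ripples) >= 5:
                c_rip = pw.coactivity(pw.normalized_xcorr(
                    spk[u].times, spk[v].times, sa.ripples, "ripple_ca1",
                    n_shuffles=n_shuffles, rng=rng))
            res["ca1_pairs"].append((u, v, c_run, c_rip))
    for u in ca1:
        for v in vc:
            if not eligible(u, v):
                continue
            c_run = pw.coactivity(pw.normalized_xcorr(
                spk[u].times, spk[v].times, sa.running, "running",
                n_shuffles=n_shuffles, rng=rng))
            c_rip = np.nan
            if len(sa.ripples) >= 5:
                c_rip = pw.coactivity(pw.normalized_xcorr(
                    spk[u].times, spk[v].times, rip_win, "ripple_ca1vc",
                    n_shuffles=n_shuffles, rng=rng))
            res["ca1vc_pairs"].append((u, v, c_run, c_rip))
    for key, name in (("ca1_pairs", "reactivation_ca1"), ("ca1vc_pairs", "reactivation_ca1vc")):
        pairs = res[key]
        if pairs:
            run_c = np.array([p[2] for p in pairs])
            rip_c = np.array([p[3] for p in pairs])
            r, p, n = pw.reactivation(run_c, rip_c)
        else:
            r, p, n = np.nan, np.nan, 0
        res[name] = {"r": r, "p": p, "n_pairs": n}
    return res


def run_experiment(
    config: SimulationConfig,
    include_pairwise: bool = False,
    include_theta: bool = False,
    n_shuffles: int = pw.N_SHUFFLES,
) -> dict:
    """Simulate a PRE/POST pair and run the full analysis chain.

    Returns a JSON-serializable report with per-session behavior, spatial,
    population, event, (optionally theta and pairwise) results and PRE vs
    POST comparisons.
    """
    pre_b, _ = simulate_session(config, "PRE")
    post_b, _ = simulate_session(config, "POST")
    pre = analyze_session(pre_b)
    post = analyze_session(post_b, immobility_threshold=pre.immobility_threshold)

    report: dict = {
        "config_seed": config.rng_seed,
        "behavior": {"PRE": pre.summary, "POST": post.summary},
    }
    rate_table = pd.concat(
        [pre.rates.assign(session="PRE"), post.rates.assign(session="POST")],
        ignore_index=True,
    )
    classes = sp.classify_units(rate_table)
    report["units"] = {
        region: classes[classes.region == region]["class"].value_counts().to_dict()
        for region in ("CA1", "VC")
    }
    spat = _spatial_metrics(pre, post)
    report["spatial"] = {
        "n_si": len(spat["si"]),
        "median_si": float(np.nanmedian(list(spat["si"].values()))) if spat["si"] else np.nan,
        "median_stability": float(np.nanmedian(list(spat["stability"].values())))
        if spat["stability"] else np.nan,
        "directionality_median": {
            k: (float(np.nanmedian(list(v.values()))) if v else np.nan)
            for k, v in spat["directionality"].items()
        },
        "within_field_rate_median": {
            k: (float(np.nanmedian(v)) if v else np.nan)
            for k, v in spat["within_field_rate"].items()
        },
        "n_fields": {k: len(v) for k, v in spat["fields"].items()},
    }

    # PRE vs POST comparisons (rank tests)
    wfr_stat, wfr_p = st.compare_groups(
        spat["within_field_rate"]["PRE"], spat["within_field_rate"]["POST"]
    )
    dir_pre = [v for v in spat["directionality"]["PRE"].values() if np.isfinite(v)]
    dir_post = [v for v in spat["directionality"]["POST"].values() if np.isfinite(v)]
    dir_stat, dir_p = st.compare_groups(dir_pre, dir_post)
    pv = _pv_metrics(pre, post)
    mua = {"PRE": _mua_metrics(pre), "POST": _mua_metrics(post)}
    post_win = (0.0, POST_IMMOBILITY_WINDOW_MIN * 60.0)
    events_rep = {
        "n_ripples": {"PRE": len(pre.ripples), "POST": len(post.ripples)},
        "n_hvs": {"PRE": len(pre.hvs), "POST": len(post.hvs)},
        "hvs_occupancy_pct": {
            "PRE": ev.hvs_occupancy(pre.hvs, pre.immobility),
            "POST": ev.hvs_occupancy(post.hvs, post.immobility, post_win),
        },
        "ripple_rate_within_hvs": {
            "PRE": ev.ripple_rate_within_hvs(pre.ripples, pre.hvs),
            "POST": ev.ripple_rate_within_hvs(
                post.ripples.clip(*post_win), post.hvs.clip(*post_win)
            ),
        },
    }
    report["population"] = pv
    report["mua"] = mua
    report["events"] = events_rep

    med = lambda v: float(np.nanmedian(v)) if len(v) else np.nan
    report["comparisons"] = {
        "within_field_rate": {
            "stat": wfr_stat, "p": wfr_p,
            "decrease": bool(
                np.isfinite(wfr_p) and wfr_p < ALPHA
                and med(spat["within_field_rate"]["POST"]) < med(spat["within_field_rate"]["PRE"])
            ),
        },
        "directionality_correlation": {
            "stat": dir_stat, "p": dir_p,
            "increase": bool(
                np.isfinite(dir_p) and dir_p < ALPHA and med(dir_post) > med(dir_pre)
            ),
        },
        "cross_trajectory_pv": {
            "increase": bool(
                np.isfinite(pv["cross_trajectory_POST"])
                and np.isfinite(pv["cross_trajectory_PRE"])
                and pv["cross_trajectory_POST"] > pv["cross_trajectory_PRE"]
            ),
        },
        "mua_peak": {
            "decrease": bool(
                np.isfinite(mua["POST"]["peak"]) and np.isfinite(mua["PRE"]["peak"])
                and mua["POST"]["peak"] < mua["PRE"]["peak"]
            ),
        },
        "hvs_occupancy": {
            "increase": bool(
                events_rep["hvs_occupancy_pct"]["POST"]
                > events_rep["hvs_occupancy_pct"]["PRE"]
            ),
        },
    }

    if include_theta:
        from . import theta as th

        report["theta"] = {}
        for label, sa in (("PRE", pre), ("POST", post)):
            spectra = th.speed_banded_psd(sa.bundle.lfp["CA1"], sa.speed, sa.laps)
            report["theta"][label] = {
                "peak_freq_by_band": {str(s.speed_band): s.theta_peak_freq for s in spectra},
                "coherence": th.theta_coherence(
                    sa.bundle.lfp["CA1"], sa.bundle.lfp["VC"], sa.running
                ),
            }
    if include_pairwise:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 777]))
        report["pairwise"] = {}
        for label, sa in (("PRE", pre), ("POST", post)):
            pr = _pairwise_metrics(sa, rng, n_shuffles)
            report["pairwise"][label] = {
                "reactivation_ca1": pr["reactivation_ca1"],
                "reactivation_ca1vc": pr["reactivation_ca1vc"],
                "n_ca1_pairs": len(pr["ca1_pairs"]),
                "n_ca1vc_pairs": len(pr["ca1vc_pairs"]),
            }
    return report


def report_hash(report: dict) -> str:
    """SHA256 of the canonical JSON serialization of a report."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    blob = json.dumps(report, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()
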