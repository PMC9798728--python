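"""End-to-end validation experiments on synthetic ground truth.

Each function runs a self-contained recovery, calibration, or effect-size
experiment against the generator and returns summary numbers.  These back
both the acceptance-style tests and the reporting script.  Problem sizes
(session length, ensemble size, seed counts) are chosen so a full pass runs
on a laptop-scale budget; docs/methods.md lists them.
"""

from __future__ import annotations

import numpy as np

from . import behavior as bhv
from . import events as ev
from . import pairwise as pw
from . import spatial as sp
from .core import ContinuousSignal, IntervalSet
from .pipeline import _pairwise_metrics, analyze_session, report_hash, run_experiment
from .synthetic import PostEffects, SimulationConfig, bundle_hash, simulate_session

__all__ = [
    "detector_recovery",
    "coactivity_null",
    "detector_false_positive_rates",
    "effect_recovery",
    "confound_removal",
    "reactivation_dissociation",
    "determinism_check",
    "spatial_oracle_agreement",
]


def _spawn(seed: int, n: int) -> list[int]:
    """Derive n child seeds below 2**31 from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


# ---------------------------------------------------------------------------
# detector recovery (injected events at the stated amplitudes)


def detector_recovery(seed: int, n_sessions: int = 3, duration: float = 360.0) -> dict:
    """Recall / precision / timing error for injected ripples (10 SD, 80 ms),
    HVS (10 SD, 8 cycles), and eHT (12 SD, 250 ms)."""
    tp = {"ripple": 0, "hvs": 0, "eht": 0}
    n_true = {"ripple": 0, "hvs": 0, "eht": 0}
    n_det = {"ripple": 0, "hvs": 0, "eht": 0}
    fp = {"ripple": 0, "hvs": 0, "eht": 0}
    terr = {"ripple": [], "eht": []}
    for s in _spawn(seed, n_sessions):
        cfg = SimulationConfig(
            session_duration=duration, n_ca1_units=6, n_vc_units=4,
            end_stop_mean=8.0, ripple_rate=12.0, hvs_rate=2.5, eht_rate=2.0,
            rng_seed=s,
        )
        bundle, truth = simulate_session(cfg, "PRE")
        sa = analyze_session(bundle)
        # ripples: match by peak time
        det = sa.ripples.peak
        n_true["ripple"] += truth.ripple_times.size
        n_det["ripple"] += det.size
        used = np.zeros(det.size, dtype=bool)
        for t in truth.ripple_times:
            if det.size == 0:
                continue
            d = np.abs(det - t)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] < 0.010:
                tp["ripple"] += 1
                used[j] = True
                terr["ripple"].append(d[j])
        fp["ripple"] += int(np.sum(~used))
        # HVS: match by interval overlap with the injected 1 s train
        hvs_len = cfg.hvs_n_cycles / cfg.hvs_cycle_freq
        n_true["hvs"] += truth.hvs_times.size
        n_det["hvs"] += len(sa.hvs)
        used_h = np.zeros(len(sa.hvs), dtype=bool)
        for t in truth.hvs_times:
            for j, (ds, de) in enumerate(sa.hvs):
                if not used_h[j] and de > t and ds < t + hvs_len:
                    tp["hvs"] += 1
                    used_h[j] = True
                    break
        fp["hvs"] += int(np.sum(~used_h))
        # eHT: injected envelope has two sub-burst peaks; match the detected
        # peak to the nearer one
        n_env = cfg.eht_duration
        bump_peaks = [0.4 * n_env / 2.0, n_env - 0.4 * n_env / 2.0]
        n_true["eht"] += truth.eht_times.size
        n_det["eht"] += len(sa.eht)
        used_e = np.zeros(len(sa.eht), dtype=bool)
        for t in truth.eht_times:
            best, bj = np.inf, -1
            for j, pk in enumerate(sa.eht.peak):
                if used_e[j]:
                    continue
                d = min(abs(pk - (t + b)) for b in bump_peaks)
                if d < best:
                    best, bj = d, j
            if bj >= 0 and best < 0.010:
                tp["eht"] += 1
                used_e[bj] = True
                terr["eht"].append(best)
        fp["eht"] += int(np.sum(~used_e))
    out = {}
    for k in ("ripple", "hvs", "eht"):
        out[f"{k}_recall"] = tp[k] / n_true[k] if n_true[k] else np.nan
        out[f"{k}_precision"] = tp[k] / n_det[k] if n_det[k] else np.nan
        out[f"{k}_n_true"] = n_true[k]
    out["ripple_time_error_ms"] = 1000 * float(np.median(terr["ripple"])) if terr["ripple"] else np.nan
    out["eht_time_error_ms"] = 1000 * float(np.median(terr["eht"])) if terr["eht"] else np.nan
    return out


# ---------------------------------------------------------------------------
# null calibration


def coactivity_null(seed: int, n_seeds: int = 50, rate: float = 5.0,
                    n_events: int = 20, event_len: float = 5.0) -> dict:
    """Pooled Z statistics of the shuffle-normalized correlogram for
    independent Poisson pairs: should be near standard normal."""
    zs = []
    starts = np.arange(n_events) * (event_len + 1.0)
    events = IntervalSet("running", starts, starts + event_len)
    duration = starts[-1] + event_len
    for s in _spawn(seed, n_seeds):
        rng = np.random.default_rng(s)
        a = np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
        b = np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
        c = pw.normalized_xcorr(a, b, events, "running", rng=rng)
        zs.extend(c.z[np.isfinite(c.z)])
    zs = np.asarray(zs)
    return {"z_mean": float(zs.mean()), "z_sd": float(zs.std()), "n_values": zs.size}


def detector_false_positive_rates(seed: int, n_seeds: int = 50,
                                  minutes_each: float = 2.0) -> dict:
    """Events per minute reported by each detector on pure Gaussian noise."""
    fs = 2000.0
    counts = {"ripple": 0, "hvs": 0, "eht": 0}
    for s in _spawn(seed, n_seeds):
        rng = np.random.default_rng(s)
        x = rng.normal(0, 15.0, int(minutes_each * 60 * fs))
        counts["ripple"] += len(ev.detect_ripples(ContinuousSignal("CA1", fs, x)))
        counts["hvs"] += len(ev.detect_hvs(ContinuousSignal("VC", fs, x)))
        counts["eht"] += len(bhv.detect_eht(ContinuousSignal("EMG", fs, x)))
    total_min = n_seeds * minutes_each
    return {f"{k}_fp_per_min": v / total_min for k, v in counts.items()}


# ---------------------------------------------------------------------------
# headline drug-effect recovery


def effect_recovery(seed: int, n_experiments: int = 50) -> dict:
    """Fraction of simulated experiments (POST: rate x0.5, directionality
    1 -> 0.5) in which the pipeline reports the four signatures: significant
    within-field rate decrease, significant directionality-correlation
    increase, increased cross-trajectory PV correlation, and reduced MUA
    cross-correlation peak."""
    hits = {"rate": 0, "directionality": 0, "pv": 0, "mua": 0, "all": 0}
    for s in _spawn(seed, n_experiments):
        cfg = SimulationConfig(
            session_duration=240.0, n_ca1_units=45, n_vc_units=10,
            rng_seed=s,
            post_effects=PostEffects(rate_scale=0.5, directionality_shift=0.5),
        )
        c = run_experiment(cfg)["comparisons"]
        ok = {
            "rate": c["within_field_rate"]["decrease"],
            "directionality": c["directionality_correlation"]["increase"],
            "pv": c["cross_trajectory_pv"]["increase"],
            "mua": c["mua_peak"]["decrease"],
        }
        for k, v in ok.items():
            hits[k] += bool(v)
        hits["all"] += all(ok.values())
    return {f"frac_{k}": v / n_experiments for k, v in hits.items()}


# ---------------------------------------------------------------------------
# speed-confound removal


def confound_removal(seed: int, n_seeds: int = 50, n_boot: int = 100) -> dict:
    """Rates purely speed-driven, POST slower than PRE: raw rates drop but
    speed-residual rates should not differ (|diff| < 2 bootstrap SE)."""

    def session(cfg_seed, speed):
        cfg = SimulationConfig(
            session_duration=240.0, n_ca1_units=8, n_vc_units=1,
            field_peak_range=(0.0, 0.0), baseline_rate=0.5, speed_gain=0.08,
            lap_speed_mean=speed, lap_speed_sd=4.0,
            ripple_rate=0.0, hvs_rate=0.0, eht_rate=0.0, rng_seed=cfg_seed,
        )
        bundle, _ = simulate_session(cfg, "PRE")
        return analyze_session(bundle), bundle

    def unit_diffs(tables, lap_idx_pre, lap_idx_post):
        """Across-unit mean residual difference for given lap subsets."""
        diffs = []
        for df in tables:
            boot = df.iloc[np.concatenate([lap_idx_pre, lap_idx_post])]
            if boot.speed.std() == 0:
                continue
            r = sp.residual_rates(boot)
            diffs.append(r.session_mean_residual["POST"] - r.session_mean_residual["PRE"])
        return float(np.mean(diffs)) if diffs else np.nan

    ok_residual = 0
    ok_raw = 0
    for s in _spawn(seed, n_seeds):
        rng = np.random.default_rng(s)
        sa_pre, b_pre = session(s, 45.0)
        sa_post, b_post = session(s + 1, 25.0)
        spikes_pre = {st.unit_id: st for st in b_pre.spikes_by_region("CA1")}
        spikes_post = {st.unit_id: st for st in b_post.spikes_by_region("CA1")}
        tables = []
        for uid in sorted(spikes_pre):
            df = sp.lap_rate_speed(
                spikes_pre[uid],
                {"PRE": sa_pre.laps, "POST": sa_post.laps},
                {"PRE": sa_pre.lin, "POST": sa_post.lin},
                {"PRE": sa_pre.speed, "POST": sa_post.speed},
                {"PRE": sa_pre.stops, "POST": sa_post.stops},
                trajectory=1,
                spikes_by_session={"PRE": spikes_pre[uid], "POST": spikes_post[uid]},
            ).reset_index(drop=True)
            tables.append(df)
        sessions = tables[0]["session"].to_numpy()
        i_pre = np.flatnonzero(sessions == "PRE")
        i_post = np.flatnonzero(sessions == "POST")
        if i_pre.size < 3 or i_post.size < 3:
            continue
        mean_diff = unit_diffs(tables, i_pre, i_post)
        # experiment-level bootstrap: laps resampled once per draw, shared
        # across units, so behavior-driven covariation is propagated
        boot = []
        for _ in range(n_boot):
            bp = i_pre[rng.integers(0, i_pre.size, i_pre.size)]
            bq = i_post[rng.integers(0, i_post.size, i_post.size)]
            d = unit_diffs(tables, bp, bq)
            if np.isfinite(d):
                boot.append(d)
        se = float(np.std(boot))
        if np.isfinite(se) and se > 0 and abs(mean_diff) < 2.0 * se:
            ok_residual += 1
        raw_pre = np.mean([t.iloc[i_pre].rate.mean() for t in tables])
        raw_post = np.mean([t.iloc[i_post].rate.mean() for t in tables])
        if raw_post < raw_pre:
            ok_raw += 1
    return {
        "frac_residual_matched": ok_residual / n_seeds,
        "frac_raw_rate_lower": ok_raw / n_seeds,
    }


# ---------------------------------------------------------------------------
# reactivation dissociation


def reactivation_dissociation(seed: int, n_seeds: int = 50) -> dict:
    """With CA1-VC coupling of ripple bursts broken (coactivity_decouple),
    within-CA1 running/ripple reactivation stays significant while CA1-VC
    does not."""
    hits, ca1_sig, ca1vc_ns = 0, 0, 0
    for s in _spawn(seed, n_seeds):
        cfg = SimulationConfig(
            session_duration=300.0, n_ca1_units=15, n_vc_units=8,
            ripple_rate=20.0, rng_seed=s,
            post_effects=PostEffects(coactivity_decouple=True),
        )
        bundle, _ = simulate_session(cfg, "POST")
        sa = analyze_session(bundle)
        pr = _pairwise_metrics(sa, np.random.default_rng(s))
        a, b = pr["reactivation_ca1"], pr["reactivation_ca1vc"]
        sig_a = np.isfinite(a["p"]) and a["p"] < 0.05
        ns_b = not (np.isfinite(b["p"]) and b["p"] < 0.05)
        ca1_sig += sig_a
        ca1vc_ns += ns_b
        hits += sig_a and ns_b
    return {
        "frac_dissociation": hits / n_seeds,
        "frac_ca1_significant": ca1_sig / n_seeds,
        "frac_ca1vc_nonsignificant": ca1vc_ns / n_seeds,
    }


# ---------------------------------------------------------------------------
# determinism & oracle agreement


def determinism_check(seed: int) -> dict:
    cfg = SimulationConfig(session_duration=60.0, n_ca1_units=4, n_vc_units=2,
                           rng_seed=seed)
    same_bundle = bundle_hash(simulate_session(cfg, "PRE")[0]) == bundle_hash(
        simulate_session(cfg, "PRE")[0])
    small = SimulationConfig(session_duration=120.0, n_ca1_units=6, n_vc_units=2,
                             ripple_rate=10.0, rng_seed=seed)
    same_report = report_hash(run_experiment(small)) == report_hash(run_experiment(small))
    return {"bundle_identical": int(same_bundle), "report_identical": int(same_report)}


def spatial_oracle_agreement(seed: int, n_draws: int = 30) -> dict:
    """Worst-case disagreement between the spatial metrics and brute-force
    oracles on random inputs, plus the analytic place-field check."""
    rng = np.random.default_rng(seed)
    si_err = 0.0
    for _ in range(n_draws):
        n = int(rng.integers(5, 80))
        rate = rng.uniform(0, 10, n)
        rate[rng.random(n) < 0.3] = 0.0
        occ = rng.uniform(0.1, 3.0, n)
        edges = np.arange(n + 1, dtype=float)
        curve = sp.RateCurve(1, edges, rate, occ, rate, occ, np.ones(n, bool), 1)
        p = occ / occ.sum()
        rbar = np.sum(p * rate)
        oracle = sum(pi * (ri / rbar) * np.log2(ri / rbar)
                     for pi, ri in zip(p, rate) if ri > 0)
        si_err = max(si_err, abs(sp.spatial_information(curve) - oracle))
    # one-hot curve
    rate = np.zeros(256)
    rate[17] = 4.0
    curve = sp.RateCurve(1, np.arange(257.0), rate, np.ones(256), rate,
                         np.ones(256), np.ones(256, bool), 1)
    onehot_err = abs(sp.spatial_information(curve) - 8.0)
    # burst index vs O(n^2) oracle
    bi_err = 0.0
    for _ in range(n_draws):
        t = np.sort(rng.uniform(0, 2, int(rng.integers(2, 60))))
        brute = np.mean([
            any(abs(t[i] - t[j]) <= 0.010 for j in range(t.size) if j != i)
            for i in range(t.size)
        ])
        bi_err = max(bi_err, abs(sp.burst_index(t) - brute))
    # analytic Gaussian place-field boundary
    x = np.arange(350) + 0.5
    sigma = 10.0
    g = 6.0 * np.exp(-0.5 * ((x - 100.0) / sigma) ** 2)
    curve = sp.RateCurve(1, np.arange(351.0), g, np.ones(350), g, np.ones(350),
                         np.ones(350, bool), 1)
    f = sp.detect_place_fields(curve)[0]
    half = sigma * np.sqrt(2 * np.log(10.0))
    fb_err = max(abs(f.start_cm - (100 - half)), abs(f.end_cm - (100 + half)))
    return {
        "si_oracle_max_abs_err": float(si_err),
        "si_onehot_abs_err": float(onehot_err),
        "burst_index_max_abs_err": float(bi_err),
        "field_boundary_err_cm": float(fb_err),
    }
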