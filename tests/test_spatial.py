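import numpy as np
import pandas as pd
import pytest

from trackephys.core import IntervalSet, LinearizedTrace, SpikeTrain
from trackephys.spatial import (
    RateCurve,
    burst_index,
    classify_units,
    compute_rate_curve,
    curve_correlation,
    detect_place_fields,
    lap_rate_speed,
    residual_rates,
    running_rate,
    spatial_information,
)


def _curve(rate, occupancy=None, valid=None, trajectory=1):
    rate = np.asarray(rate, dtype=float)
    n = rate.size
    occ = np.ones(n) if occupancy is None else np.asarray(occupancy, dtype=float)
    v = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    edges = np.arange(n + 1, dtype=float)
    return RateCurve(trajectory, edges, rate, occ, rate.copy(), occ.copy(), v, 1)


def _si_oracle(rate, occ):
    """Brute-force direct summation of the bits/spike formula."""
    p = occ / occ.sum()
    rbar = np.sum(p * rate)
    out = 0.0
    for pi, ri in zip(p, rate):
        if ri > 0:
            out += pi * (ri / rbar) * np.log2(ri / rbar)
    return out


class TestSpatialInformation:
    def test_uniform_rate_zero_information(self):
        assert spatial_information(_curve(np.full(100, 4.0))) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [16, 256])
    def test_one_hot_curve_gives_log2_n(self, n):
        rate = np.zeros(n)
        rate[3] = 7.0
        assert spatial_information(_curve(rate)) == pytest.approx(np.log2(n), abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(5, 60)
            rate = rng.uniform(0, 10, n)
            rate[rng.random(n) < 0.3] = 0.0
            occ = rng.uniform(0.1, 3.0, n)
            got = spatial_information(_curve(rate, occ))
            assert got == pytest.approx(_si_oracle(rate, occ), abs=1e-12)

    def test_scale_invariance(self, rng):
        rate = rng.uniform(0, 10, 50)
        occ = rng.uniform(0.5, 2.0, 50)
        a = spatial_information(_curve(rate, occ))
        b = spatial_information(_curve(rate * 17.3, occ))
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_mean_rate_is_missing(self):
        assert np.isnan(spatial_information(_curve(np.zeros(30))))


class TestBurstIndex:
    def test_regular_5ms_train_fully_bursty(self):
        t = np.arange(0, 1, 0.005)
        assert burst_index(t) == 1.0

    def test_regular_50ms_train_not_bursty(self):
        t = np.arange(0, 1, 0.050)
        assert burst_index(t) == 0.0

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(20):
            t = np.sort(rng.uniform(0, 2, rng.integers(2, 80)))
            brute = np.mean([
                any(abs(t[i] - t[j]) <= 0.010 for j in range(t.size) if j != i)
                for i in range(t.size)
            ])
            assert burst_index(t) == pytest.approx(brute)

    def test_single_spike_missing(self):
        assert np.isnan(burst_index(np.array([1.0])))


class TestPlaceFields:
    def _gauss_curve(self, peak=6.0, center=100.0, sigma=10.0, n=350):
        x = np.arange(n) + 0.5
        return _curve(peak * np.exp(-0.5 * ((x - center) / sigma) ** 2))

    def test_gaussian_bump_boundaries_at_ten_percent(self):
        """10 %-of-peak crossings of a Gaussian: center +- sigma*sqrt(2 ln 10)."""
        sigma = 10.0
        fields = detect_place_fields(self._gauss_curve(sigma=sigma))
        assert len(fields) == 1
        half = sigma * np.sqrt(2 * np.log(10.0))
        f = fields[0]
        assert f.start_cm == pytest.approx(100.0 - half, abs=1.0)
        assert f.end_cm == pytest.approx(100.0 + half, abs=1.0)
        assert f.length == pytest.approx(2 * half, abs=2.0)
        assert f.peak_rate == pytest.approx(6.0, rel=0.01)

    def test_subthreshold_peak_yields_no_field(self):
        assert detect_place_fields(self._gauss_curve(peak=2.5)) == []

    def test_nearby_fields_merged(self):
        x = np.arange(350) + 0.5
        # sigma 2 bumps at 100 and 111: 10 % boundaries ~4.3 cm from the
        # centers leave a ~4 cm gap, below the 5 cm merge rule
        rate = 6.0 * np.exp(-0.5 * ((x - 100) / 2.0) ** 2)
        rate += 6.0 * np.exp(-0.5 * ((x - 111) / 2.0) ** 2)
        fields = detect_place_fields(_curve(rate))
        assert len(fields) == 1
        assert fields[0].start_cm < 100 < 111 < fields[0].end_cm

    def test_distant_fields_kept_separate(self):
        x = np.arange(350) + 0.5
        rate = 6.0 * np.exp(-0.5 * ((x - 80) / 5.0) ** 2)
        rate += 8.0 * np.exp(-0.5 * ((x - 250) / 5.0) ** 2)
        fields = detect_place_fields(_curve(rate))
        assert len(fields) == 2

    def test_idempotent_on_detected_mask(self):
        fields = detect_place_fields(self._gauss_curve())
        again = detect_place_fields(self._gauss_curve())
        assert [(f.start_cm, f.end_cm) for f in fields] == [
            (f.start_cm, f.end_cm) for f in again]


class TestClassification:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["unit_id", "region", "session", "trajectory", "rate"])

    def test_active_silent_interneuron_rules(self):
        t = self._table([
            ("a", "CA1", "PRE", 1, 1.0), ("a", "CA1", "PRE", -1, 0.1),
            ("b", "CA1", "PRE", 1, 0.3), ("b", "CA1", "PRE", -1, 0.3),
            ("c", "CA1", "PRE", 1, 7.0), ("c", "CA1", "PRE", -1, 7.0),
            ("d", "VC", "PRE", 1, 30.0), ("d", "VC", "PRE", -1, 28.0),
        ])
        cls = classify_units(t).set_index("unit_id")["class"]
        assert cls["a"] == "active"
        assert cls["b"] == "silent"
        assert cls["c"] == "interneuron"
        assert cls["d"] == "excluded"

    def test_active_in_either_session_counts(self):
        t = self._table([
            ("a", "CA1", "PRE", 1, 0.2), ("a", "CA1", "POST", 1, 0.8),
        ])
        assert classify_units(t)["class"].iloc[0] == "active"

    def test_high_rate_one_trajectory_only_is_not_interneuron(self):
        t = self._table([
            ("a", "CA1", "PRE", 1, 8.0), ("a", "CA1", "PRE", -1, 1.0),
        ])
        assert classify_units(t)["class"].iloc[0] == "active"


class TestRateCurve:
    def _setup_uniform(self, rate_hz=5.0, duration=400.0, rng=None):
        rng = rng or np.random.default_rng(0)
        fs = 33.0
        t = np.arange(0, duration, 1 / fs)
        # sawtooth traversals, constant speed 35 cm/s over 350 cm
        period = 2 * 350.0 / 35.0
        ph = (t % period) / period
        pos = np.where(ph < 0.5, 2 * ph, 2 * (1 - ph)) * 350.0
        d = np.where(ph < 0.5, 1, -1)
        lin = LinearizedTrace(t, pos, d, 350.0)
        # laps = the half-periods
        n_lap = int(duration / (period / 2))
        starts = np.arange(n_lap) * period / 2
        laps = IntervalSet("lap", starts, starts + period / 2,
                           attrs={"direction": np.where(np.arange(n_lap) % 2 == 0, 1, -1)})
        spikes = np.sort(rng.uniform(0, duration, rng.poisson(rate_hz * duration)))
        st = SpikeTrain("u", "CA1", spikes)
        return st, lin, laps, IntervalSet("stop")

    def test_homogeneous_poisson_gives_flat_curve(self):
        st, lin, laps, stops = self._setup_uniform()
        c = compute_rate_curve(st, lin, laps, stops, 1, reward_sites=[0.0, 350.0])
        vals = c.rate[c.valid]
        assert np.nanmean(vals) == pytest.approx(5.0, rel=0.1)
        assert np.nanstd(vals) < 1.5

    def test_zero_spikes_all_zero(self):
        st, lin, laps, stops = self._setup_uniform()
        st = SpikeTrain("u", "CA1", np.empty(0))
        c = compute_rate_curve(st, lin, laps, stops, 1, reward_sites=[0.0, 350.0])
        assert np.nansum(c.rate[c.valid]) == 0.0

    def test_spike_count_conservation(self):
        """Unsmoothed spike counts equal the included running spikes."""
        st, lin, laps, stops = self._setup_uniform()
        c = compute_rate_curve(st, lin, laps, stops, 1, reward_sites=[0.0, 350.0])
        keep = laps.attrs["direction"] == 1
        sel = IntervalSet("lap", laps.start[keep], laps.end[keep])
        assert c.raw_counts.sum() == sel.restrict(st.times).size

    def test_reward_adjacent_bins_masked(self):
        st, lin, laps, stops = self._setup_uniform()
        c = compute_rate_curve(st, lin, laps, stops, 1, reward_sites=[0.0, 350.0])
        assert not c.valid[:10].any() and not c.valid[-10:].any()

    def test_generator_field_center_recovered(self, pre_session, pre_analysis):
        """Curve argmax lands within 3 cm of the true field center."""
        bundle, truth = pre_session
        sa = pre_analysis
        errs = []
        for i in range(len(truth.ca1_center_traj1)):
            c = sa.curves[(f"ca1_{i}", 1)]
            center = truth.ca1_center_traj1[i]
            if not (15 < center < 335) or truth.ca1_peak[i] < 5:
                continue
            if not np.isfinite(c.rate[c.valid]).any():
                continue
            idx = np.nanargmax(np.where(c.valid, c.rate, -np.inf))
            errs.append(abs(c.centers[idx] - center))
        assert len(errs) >= 5
        assert np.median(errs) <= 3.0


class TestCurveCorrelation:
    def test_identical_curves(self, rng):
        r = rng.uniform(0, 8, 100)
        assert curve_correlation(_curve(r), _curve(r.copy())) == pytest.approx(1.0)

    def test_negated_about_mean(self, rng):
        r = rng.uniform(0, 8, 100)
        neg = 2 * r.mean() - r
        assert curve_correlation(_curve(r), _curve(neg)) == pytest.approx(-1.0)

    def test_constant_curve_missing(self):
        assert np.isnan(curve_correlation(_curve(np.full(50, 2.0)), _curve(np.arange(50.0))))

    def test_too_few_overlapping_bins_missing(self, rng):
        v = np.zeros(50, dtype=bool)
        v[:5] = True
        a = _curve(rng.uniform(0, 5, 50), valid=v)
        assert np.isnan(curve_correlation(a, _curve(rng.uniform(0, 5, 50))))

    def test_mismatched_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            curve_correlation(_curve(np.ones(50)), _curve(np.ones(60)))


class TestResidualRates:
    def test_exact_linear_relation_zero_residuals(self):
        s = np.array([20.0, 30, 40, 50, 35, 45])
        df = pd.DataFrame({
            "session": ["PRE"] * 3 + ["POST"] * 3,
            "rate": 0.1 * s + 2.0,
            "speed": s,
        })
        reg = residual_rates(df)
        assert reg.slope == pytest.approx(0.1, abs=1e-10)
        assert reg.intercept == pytest.approx(2.0, abs=1e-9)
        assert abs(reg.session_mean_residual["PRE"]) < 1e-10
        assert abs(reg.session_mean_residual["POST"]) < 1e-10

    def test_residuals_sum_to_zero(self, rng):
        df = pd.DataFrame({
            "session": ["PRE"] * 10 + ["POST"] * 10,
            "rate": rng.uniform(0, 5, 20),
            "speed": rng.uniform(10, 60, 20),
        })
        reg = residual_rates(df)
        assert reg.lap_table["residual"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_identical_speeds_degenerate(self):
        df = pd.DataFrame({
            "session": ["PRE"] * 4,
            "rate": [1.0, 2.0, 3.0, 4.0],
            "speed": [30.0] * 4,
        })
        reg = residual_rates(df)
        assert reg.degenerate
        assert reg.slope == 0.0
        assert reg.intercept == pytest.approx(2.5)

    def test_too_few_laps_rejected(self):
        df = pd.DataFrame({"session": ["PRE"], "rate": [1.0], "speed": [30.0]})
        with pytest.raises(ValueError):
            residual_rates(df)


def test_running_rate_uses_direction_and_stops():
    laps = IntervalSet("lap", [0.0, 20.0], [10.0, 30.0],
                       attrs={"direction": np.array([1, -1])})
    stops = IntervalSet("stop", [5.0], [10.0])
    st = SpikeTrain("u", "CA1", np.array([1.0, 2.0, 6.0, 25.0]))
    # traj 1: lap [0,10) minus stop [5,10) -> 5 s with spikes at 1, 2
    assert running_rate(st, laps, stops, 1) == pytest.approx(2 / 5.0)
    assert running_rate(st, laps, stops, -1) == pytest.approx(1 / 10.0)
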