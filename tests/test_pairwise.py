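import numpy as np
import pytest

from trackephys.core import ContinuousSignal, IntervalSet, LinearizedTrace
from trackephys.pairwise import (
    NormalizedCorrelogram,
    coactivity,
    mua_trace,
    mua_xcorr,
    normalized_xcorr,
    reactivation,
    ripple_windows,
    triggered_average,
)


def _poisson_train(rng, rate, duration):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


def _long_events(n=20, length=5.0, gap=1.0):
    starts = np.arange(n) * (length + gap)
    return IntervalSet("running", starts, starts + length)


class TestNormalizedXcorr:
    def test_identical_trains_strong_zero_lag(self, rng):
        """Perfect coincidence across many short events: Z(0) > 5."""
        peaks = np.arange(100) * 2.0 + 0.5
        events = IntervalSet("ripple", peaks - 0.05, peaks + 0.05)
        train = peaks + rng.normal(0, 0.004, peaks.size)
        train = np.sort(np.concatenate([train, train + 0.002]))
        c = normalized_xcorr(train, train, events, "ripple_ca1", rng=rng)
        i0 = np.argmin(np.abs(c.lags))
        assert c.z[i0] > 5

    def test_independent_poisson_null_calibrated(self, rng):
        zs = []
        for _ in range(10):
            a = _poisson_train(rng, 5.0, 120.0)
            b = _poisson_train(rng, 5.0, 120.0)
            c = normalized_xcorr(a, b, _long_events(), "running", rng=rng)
            zs.extend(c.z[np.isfinite(c.z)])
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.25
        assert 0.7 < zs.std() < 1.3

    def test_shifted_train_peak_at_shift(self, rng):
        """The boxcar smoothing turns a delta into a plateau, so locate the
        peak by the positive-Z center of mass."""
        a = _poisson_train(rng, 8.0, 100.0)
        b = a + 0.05
        c = normalized_xcorr(a, b, _long_events(16, 6.0), "running", rng=rng)
        w = np.where(np.isfinite(c.z) & (c.z > 0), c.z, 0.0)
        com = np.sum(c.lags * w) / np.sum(w)
        assert com == pytest.approx(0.05, abs=0.015)

    def test_rotate_and_rebin_agree(self, rng):
        """The fast rotation path and the literal continuous re-binning path
        estimate the same correlogram."""
        a = _poisson_train(rng, 6.0, 60.0)
        b = np.sort(np.concatenate([a[::2] + 0.01, _poisson_train(rng, 3.0, 60.0)]))
        ev = _long_events(10, 5.0)
        z1 = normalized_xcorr(a, b, ev, "running", rng=np.random.default_rng(1)).z
        z2 = normalized_xcorr(a, b, ev, "running", rng=np.random.default_rng(2),
                              method="rebin").z
        ok = np.isfinite(z1) & np.isfinite(z2)
        assert np.corrcoef(z1[ok], z2[ok])[0, 1] > 0.85
        assert abs(z1[ok].mean() - z2[ok].mean()) < 0.3

    def test_shuffle_determinism(self, rng):
        a = _poisson_train(rng, 5.0, 60.0)
        b = _poisson_train(rng, 5.0, 60.0)
        ev = _long_events(10, 5.0)
        z1 = normalized_xcorr(a, b, ev, "running", rng=np.random.default_rng(9)).z
        z2 = normalized_xcorr(a, b, ev, "running", rng=np.random.default_rng(9)).z
        assert np.allclose(z1, z2, equal_nan=True)

    def test_shuffle_count_convergence(self, rng):
        """Coactivity moves < 0.2 between 200 and 1000 shuffles."""
        a = _poisson_train(rng, 8.0, 80.0)
        b = np.sort(np.concatenate([a[::8] + 0.02, _poisson_train(rng, 5.0, 80.0)]))
        ev = _long_events(13, 5.0)
        c200 = coactivity(normalized_xcorr(a, b, ev, "running", n_shuffles=200,
                                           rng=np.random.default_rng(3)))
        c1000 = coactivity(normalized_xcorr(a, b, ev, "running", n_shuffles=1000,
                                            rng=np.random.default_rng(4)))
        assert abs(c200 - c1000) < 0.2

    def test_no_events_rejected(self, rng):
        with pytest.raises(ValueError):
            normalized_xcorr(np.arange(5.0), np.arange(5.0), IntervalSet("e"), "running")

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            normalized_xcorr(np.arange(5.0), np.arange(5.0), _long_events(2), "sleep")


class TestCoactivity:
    def _corr(self, z, context="running"):
        lags = (np.arange(z.size) - z.size // 2) * 0.01
        return NormalizedCorrelogram(lags, z, z, np.zeros_like(z), np.ones_like(z),
                                     200, context)

    def test_flat_z_two_gives_two(self):
        assert coactivity(self._corr(np.full(101, 2.0))) == pytest.approx(2.0)

    def test_antisymmetric_z_gives_zero(self):
        z = np.linspace(-3, 3, 101)
        assert coactivity(self._corr(z)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_mean_oracle(self, rng):
        z = rng.standard_normal(101)
        lags = (np.arange(101) - 50) * 0.01
        expected = z[np.abs(lags) <= 0.1 + 1e-9].mean()
        assert coactivity(self._corr(z)) == pytest.approx(expected)

    def test_all_missing_window_missing(self):
        z = np.full(101, np.nan)
        assert np.isnan(coactivity(self._corr(z)))


class TestReactivation:
    def test_identical_coactivities_r_one(self, rng):
        c = rng.standard_normal(40)
        r, p, n = reactivation(c, c.copy())
        assert r == pytest.approx(1.0)
        assert n == 40

    def test_permuted_near_zero(self, rng):
        c = rng.standard_normal(400)
        r, _, _ = reactivation(c, rng.permutation(c))
        assert abs(r) < 2 / np.sqrt(400) * 2.5

    def test_too_few_pairs_missing(self):
        r, p, n = reactivation(np.arange(5.0), np.arange(5.0))
        assert np.isnan(r) and n == 5


class TestMua:
    def test_trace_normalized_and_bounded(self, rng):
        trains = [_poisson_train(rng, 20.0, 50.0) for _ in range(4)]
        t, m = mua_trace(trains, 0.0, 50.0)
        assert m.min() >= 0.0 and m.max() <= 1.0 + 1e-12

    def test_identical_mua_peak_one_at_zero(self, rng):
        trains = [_poisson_train(rng, 30.0, 60.0) for _ in range(3)]
        t, m = mua_trace(trains, 0.0, 60.0)
        xc = mua_xcorr(t, m, m.copy(), IntervalSet("running", [2.0], [58.0]))
        val, lag = xc.peak
        assert val == pytest.approx(1.0, abs=1e-9)
        assert lag == 0.0

    def test_delayed_mua_peak_at_delay(self, rng):
        trains = [_poisson_train(rng, 30.0, 60.0) for _ in range(3)]
        t, m = mua_trace(trains, 0.0, 60.0)
        shifted = np.roll(m, 10)  # +100 ms
        xc = mua_xcorr(t, m, shifted, IntervalSet("running", [2.0], [58.0]))
        assert xc.peak[1] == pytest.approx(0.1, abs=0.011)

    def test_swap_symmetry_with_lag_negation(self, rng):
        trains = [_poisson_train(rng, 25.0, 60.0) for _ in range(3)]
        t, a = mua_trace(trains, 0.0, 60.0)
        _, b = mua_trace([_poisson_train(rng, 25.0, 60.0)], 0.0, 60.0)
        run = IntervalSet("running", [2.0], [58.0])
        ab = mua_xcorr(t, a, b, run)
        ba = mua_xcorr(t, b, a, run)
        assert np.allclose(ab.mean, ba.mean[::-1], equal_nan=True)

    def test_bounded_in_unit_interval(self, rng):
        trains = [_poisson_train(rng, 25.0, 60.0) for _ in range(2)]
        t, a = mua_trace(trains, 0.0, 60.0)
        _, b = mua_trace([_poisson_train(rng, 25.0, 60.0)], 0.0, 60.0)
        xc = mua_xcorr(t, a, b, IntervalSet("running", [2.0], [58.0]))
        ok = np.isfinite(xc.mean)
        assert np.all(xc.mean[ok] <= 1.0 + 1e-9) and np.all(xc.mean[ok] >= -1.0 - 1e-9)

    def test_short_periods_skipped(self, rng):
        trains = [_poisson_train(rng, 25.0, 10.0)]
        t, m = mua_trace(trains, 0.0, 10.0)
        xc = mua_xcorr(t, m, m, IntervalSet("running", [0.0], [1.5]))
        assert xc.n_events == 0


class TestTriggeredAverage:
    def test_identical_profiles_zero_se(self):
        fs = 1000.0
        t = np.arange(0, 60, 1 / fs)
        profile_f = 2.0
        sig = ContinuousSignal("s", fs, np.sin(2 * np.pi * profile_f * t))
        trig = np.arange(5.0, 55.0, 1.0)  # aligned to the 2 Hz cycle
        ta = triggered_average("signal", sig, trig, (-0.2, 0.2), bin_size=0.01,
                               session_duration=60.0)
        assert np.allclose(ta.se, 0.0, atol=1e-9)
        expected = np.sin(2 * np.pi * profile_f * ta.lags)
        assert np.allclose(ta.mean, expected, atol=0.05)

    def test_position_rezeroed_at_lag_zero(self):
        t = np.arange(0, 100, 1 / 33.0)
        lin = LinearizedTrace(t, 3.0 * t, np.ones_like(t, dtype=int), 350.0)
        ta = triggered_average("position", lin, np.array([20.0, 50.0]), (-1.0, 1.0),
                               session_duration=100.0)
        i0 = np.argmin(np.abs(ta.lags))
        assert abs(ta.mean[i0]) < 0.1
        assert ta.se[i0] == pytest.approx(0.0, abs=0.05)

    def test_rate_mode_recovers_injected_bump(self, rng):
        trig = np.arange(10.0, 290.0, 10.0)
        cells = []
        for _ in range(5):
            bg = _poisson_train(rng, 2.0, 300.0)
            bump = np.concatenate([tt + rng.normal(0.1, 0.05, 8) for tt in trig])
            cells.append(np.sort(np.concatenate([bg, bump])))
        ta = triggered_average("rate", cells, trig, (-5.0, 5.0), bin_size=0.05,
                               session_duration=300.0)
        val, lag = ta.peak
        assert abs(lag - 0.1) <= 0.1
        assert val > 2.0

    def test_partial_windows_dropped(self):
        fs = 100.0
        sig = ContinuousSignal("s", fs, np.zeros(1000))
        ta = triggered_average("signal", sig, np.array([0.5, 5.0]), (-1.0, 1.0),
                               session_duration=10.0)
        assert ta.n_events == 1

    def test_no_valid_triggers_missing(self):
        sig = ContinuousSignal("s", 100.0, np.zeros(500))
        ta = triggered_average("signal", sig, np.array([0.1]), (-1.0, 1.0),
                               session_duration=5.0)
        assert ta.n_events == 0
        assert np.all(np.isnan(ta.mean))


def test_ripple_triggered_vc_mua_baseline_subtracted(rng):
    """A VC MUA bump at every ripple peak shows up at lag 0 relative to the
    flanking baselines; triggers without full baseline coverage are
    dropped."""
    from trackephys.pairwise import ripple_triggered_vc_mua

    t = np.arange(0, 60, 0.01)
    mua = np.full(t.size, 0.2)
    peaks = np.arange(2.0, 58.0, 2.0)
    for pk in peaks:
        mua += 0.5 * np.exp(-0.5 * ((t - pk) / 0.015) ** 2)
    ta = ripple_triggered_vc_mua(t, mua, np.concatenate([peaks, [0.05]]))
    assert ta.n_events == peaks.size  # the 0.05 s trigger lacks baseline room
    i0 = np.argmin(np.abs(ta.lags))
    assert ta.mean[i0] == pytest.approx(0.5, abs=0.05)
    # flanks are near zero after baseline subtraction
    assert abs(ta.mean[0]) < 0.1 and abs(ta.mean[-1]) < 0.1


def test_ripple_windows_centered_on_peaks():
    rip = IntervalSet("ripple", [10.0, 20.0], [10.1, 20.1], [10.05, 20.05])
    w = ripple_windows(rip)
    assert np.allclose(w.start, [9.05, 19.05])
    assert np.allclose(w.end, [11.05, 21.05])
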