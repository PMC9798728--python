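import numpy as np
import pytest

from trackephys.behavior import (
    behavior_summary,
    compute_speed,
    detect_eht,
    detect_immobility,
    detect_stops,
    linearize,
    segment_laps,
)
from trackephys.core import (
    ContinuousSignal,
    IntervalSet,
    LinearizedTrace,
    PositionTrace,
    SpeedTrace,
)
from trackephys.synthetic import track_polyline


def _line_trace(speed_cm_s, duration=20.0, fs=33.0):
    t = np.arange(0, duration, 1 / fs)
    return PositionTrace(t, speed_cm_s * t, np.zeros_like(t))


class TestComputeSpeed:
    def test_constant_velocity(self):
        sp = compute_speed(_line_trace(40.0))
        interior = sp.speed[70:-70]
        assert np.all(np.abs(interior - 40.0) < 0.1)

    def test_stationary(self):
        t = np.arange(0, 10, 1 / 33)
        sp = compute_speed(PositionTrace(t, np.full_like(t, 5.0), np.full_like(t, 2.0)))
        assert np.allclose(sp.speed, 0.0)

    def test_nonmonotone_rejected(self):
        with pytest.raises(ValueError):
            PositionTrace(np.array([0.0, 1.0, 0.5]), np.zeros(3), np.zeros(3))

    def test_generator_speed_recovered(self, pre_session):
        """Position-derived running speed matches the generative speed."""
        from trackephys.core import gaussian_smooth

        bundle, truth = pre_session
        sp = compute_speed(bundle.positions)
        # compare against the generative speed passed through the same
        # 0.5 s smoothing window (like for like)
        truth_s = gaussian_smooth(truth.speed_at_pos, 0.5 * 33)
        assert np.corrcoef(sp.speed, truth_s)[0, 1] > 0.99
        run = truth_s > 15
        assert np.mean(sp.speed[run]) == pytest.approx(np.mean(truth_s[run]), rel=0.05)


class TestLinearize:
    def test_points_on_skeleton_recover_arc_length(self):
        poly = track_polyline(350.0)
        # traverse at 35 cm/s: arc positions are known exactly
        t = np.arange(0, 10, 1 / 33)
        arc = 35.0 * t
        from trackephys.synthetic import _arc_to_xy

        xy = _arc_to_xy(arc, poly)
        lin = linearize(PositionTrace(t, xy[:, 0], xy[:, 1]), poly)
        assert np.max(np.abs(lin.pos1d - arc)) < 0.5
        assert np.all(lin.direction[20:-20] == 1)

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            linearize(_line_trace(10.0), np.array([[0.0, 0.0]]))

    def test_far_points_marked_undefined(self):
        poly = track_polyline(350.0)
        t = np.arange(0, 5, 1 / 33)
        pos = PositionTrace(t, np.full_like(t, 50.0), np.full_like(t, 80.0))
        lin = linearize(pos, poly, projection_tolerance=5.0)
        assert np.all(lin.direction == 0)


class TestImmobility:
    def _alternating_speed(self):
        # 2 s at 0, 2 s at 50, repeated; 100 Hz time base
        t = np.arange(0, 20, 0.01)
        v = np.where((t // 2).astype(int) % 2 == 0, 0.0, 50.0)
        return SpeedTrace(t, v)

    def test_threshold_recovers_zero_blocks(self):
        sp = self._alternating_speed()
        lin = LinearizedTrace(sp.t, np.zeros_like(sp.t), np.zeros_like(sp.t, dtype=int), 350.0)
        iv, thr = detect_immobility(sp, lin, [0.0], threshold=10.0)
        assert thr == 10.0
        assert len(iv) == 5
        assert np.allclose(iv.durations, 2.0, atol=0.05)

    def test_sub_half_second_gap_merged(self):
        t = np.arange(0, 10, 0.01)
        v = np.full_like(t, 50.0)
        v[(t >= 1) & (t < 3)] = 0.0
        v[(t >= 3.3) & (t < 5)] = 0.0  # 0.3 s gap -> combined
        sp = SpeedTrace(t, v)
        lin = LinearizedTrace(t, np.zeros_like(t), np.zeros_like(t, dtype=int), 350.0)
        iv, _ = detect_immobility(sp, lin, [0.0], threshold=10.0)
        assert len(iv) == 1
        assert iv.start[0] == pytest.approx(1.0, abs=0.05)
        assert iv.end[0] == pytest.approx(5.0, abs=0.05)

    def test_empty_speed_rejected(self):
        lin = LinearizedTrace(np.empty(0), np.empty(0), np.empty(0), 350.0)
        with pytest.raises(ValueError):
            detect_immobility(SpeedTrace(np.empty(0), np.empty(0)), lin, [0.0])

    def test_generator_immobility_recovered(self, pre_session, pre_analysis):
        """Detected immobility overlaps ground truth (Jaccard > 0.9)."""
        _, truth = pre_session
        gt = IntervalSet("gt", *zip(*truth.immobility))
        det = pre_analysis.immobility
        t = np.arange(0, pre_analysis.bundle.duration, 0.05)
        a, b = gt.contains(t), det.contains(t)
        jaccard = np.sum(a & b) / np.sum(a | b)
        assert jaccard > 0.9


class TestLaps:
    def _lin(self, pos, fs=33.0):
        t = np.arange(len(pos)) / fs
        d = np.sign(np.gradient(pos))
        return LinearizedTrace(t, pos, d.astype(int), 350.0)

    def test_single_sweep_is_one_lap(self):
        pos = np.linspace(0, 350, 300)
        laps = segment_laps(self._lin(pos))
        assert len(laps) == 1
        assert laps.attrs["direction"][0] == 1

    def test_back_and_forth_n_laps_alternating(self):
        one = np.concatenate([np.linspace(0, 350, 300), np.linspace(350, 0, 300)])
        pos = np.tile(one, 3)
        laps = segment_laps(self._lin(pos))
        assert len(laps) == 6
        assert list(laps.attrs["direction"]) == [1, -1] * 3

    def test_incomplete_traversal_not_a_lap(self):
        pos = np.concatenate([np.linspace(0, 200, 200), np.linspace(200, 0, 200)])
        laps = segment_laps(self._lin(pos))
        assert len(laps) == 0

    def test_lap_count_invariant_to_time_shift(self):
        pos = np.concatenate([np.linspace(0, 350, 300), np.linspace(350, 0, 300)])
        lin = self._lin(pos)
        shifted = LinearizedTrace(lin.t + 1000.0, lin.pos1d, lin.direction, 350.0)
        assert len(segment_laps(lin)) == len(segment_laps(shifted))

    def test_generator_lap_count_matches_truth(self, pre_session, pre_analysis):
        _, truth = pre_session
        assert len(pre_analysis.laps) == len(truth.laps)


class TestEht:
    FS = 2000.0

    def _noise(self, seed, duration=600.0):
        r = np.random.default_rng(seed)
        return ContinuousSignal("EMG", self.FS, r.normal(0, 10.0, int(duration * self.FS)))

    def _with_burst(self, t0=100.0, amp_sd=12.0, seed=0):
        """A 250 ms burst with two 12 SD envelope peaks 0.12 s apart.

        Returns (signal, envelope_sd_units, start_index)."""
        sig = self._noise(seed)
        from trackephys.core import bandpass

        sd = np.std(bandpass(sig.samples, self.FS, 20, 60))
        n = int(0.25 * self.FS)
        nb = int(0.10 * self.FS)
        env = np.zeros(n)
        env[:nb] = np.hanning(nb)
        c2 = int(0.12 * self.FS) + nb // 2 - nb // 2  # second bump: peak 0.12 s later
        o2 = int(0.12 * self.FS)
        env[o2:o2 + nb] = np.maximum(env[o2:o2 + nb], np.hanning(nb))
        tt = np.arange(n) / self.FS
        i0 = int(t0 * self.FS)
        sig.samples[i0:i0 + n] += amp_sd * sd * env * np.sin(2 * np.pi * 40 * tt)
        return sig, amp_sd * env, i0

    def test_pure_noise_yields_no_events(self):
        for seed in range(3):
            assert len(detect_eht(self._noise(seed))) == 0

    def test_injected_burst_detected_once_with_duration(self):
        sig, env_sd, i0 = self._with_burst()
        ev = detect_eht(sig)
        assert len(ev) == 1
        # both envelope peaks fall inside the detected event
        peak_times = (i0 + np.array([np.argmax(env_sd[:300]),
                                     240 + np.argmax(env_sd[240:])])) / self.FS
        assert ev.start[0] <= peak_times.min() and ev.end[0] >= peak_times.max()
        # duration within +-20 ms of the injected envelope's 3.5 SD crossings
        above = np.flatnonzero(env_sd > 3.5)
        expected = (above[-1] - above[0]) / self.FS
        assert ev.durations[0] == pytest.approx(expected, abs=0.020)

    def test_single_isolated_peak_is_not_an_event(self):
        sig = self._noise(1)
        from trackephys.core import bandpass

        sd = np.std(bandpass(sig.samples, self.FS, 20, 60))
        n = int(0.05 * self.FS)  # 2 cycles at 40 Hz: one surviving merged peak
        tt = np.arange(n) / self.FS
        i0 = int(50.0 * self.FS)
        sig.samples[i0:i0 + n] += 12 * sd * np.hanning(n) * np.sin(2 * np.pi * 40 * tt)
        assert len(detect_eht(sig)) == 0

    def test_amplitude_scaling_invariance(self):
        sig, _, _ = self._with_burst(seed=2)
        ev1 = detect_eht(sig)
        scaled = ContinuousSignal("EMG", self.FS, sig.samples * 7.3)
        ev2 = detect_eht(scaled)
        assert len(ev1) == len(ev2) == 1
        assert np.allclose(ev1.start, ev2.start)
        assert np.allclose(ev1.end, ev2.end)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_eht(ContinuousSignal("EMG", 100.0, np.zeros(1000)))


def test_summary_reports_rates(pre_analysis):
    s = pre_analysis.summary
    assert s["n_laps"] > 0
    assert 0 < s["percent_immobile"] < 100
    assert s["median_running_speed_cm_s"] > 10


def test_immobility_and_running_partition(pre_analysis):
    """Immobility plus its complement cover the session without overlap."""
    sa = pre_analysis
    comp = sa.immobility.complement(0.0, sa.bundle.duration)
    total = sa.immobility.total_duration + comp.total_duration
    assert total == pytest.approx(sa.bundle.duration, abs=1e-6)


def test_stop_mask_requires_sustained_slowness():
    t = np.arange(0, 10, 0.01)
    v = np.full_like(t, 50.0)
    v[(t >= 2.0) & (t < 2.2)] = 0.0  # only 0.2 s below threshold
    v[(t >= 5.0) & (t < 6.0)] = 0.0
    stops = detect_stops(SpeedTrace(t, v))
    assert len(stops) == 1
    assert stops.start[0] == pytest.approx(5.0, abs=0.05)
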