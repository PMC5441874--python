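"""Turn detection, pirouette/run segmentation, bearings, prediction intervals."""

import numpy as np
import pytest
from scipy import stats

from odornav import behavior as bh
from odornav import odor_field as of
from odornav import synthetic as syn

FIELD = of.GradientParams()


def make_track(x, y, rate_hz=1.0, t0=0.0):
    x = np.asarray(x, float)
    n = x.size
    t = t0 + np.arange(n) / rate_hz
    return bh.Trajectory(t, x, np.asarray(y, float), rate_hz)


def track_with_heading_change(angle_deg):
    """Straight 1-Hz track with one instantaneous heading change."""
    step = 0.05  # cm/s, well above the low-speed threshold
    seg1 = np.arange(10) * step
    theta = np.radians(angle_deg)
    x = list(seg1)
    y = [0.0] * 10
    for _ in range(10):
        x.append(x[-1] + step * np.cos(theta))
        y.append(y[-1] + step * np.sin(theta))
    return make_track(x, y)


class TestSmoothTrack:
    def test_zero_window_is_identity(self):
        tr = make_track(np.random.default_rng(0).random(30), np.zeros(30))
        sm = bh.smooth_track(tr, 0)
        np.testing.assert_array_equal(sm.x, tr.x)

    def test_constant_position_unchanged(self):
        tr = make_track(np.full(50, 1.5), np.full(50, -0.5), rate_hz=10)
        sm = bh.smooth_track(tr, 10)
        np.testing.assert_allclose(sm.x, 1.5)
        np.testing.assert_allclose(sm.y, -0.5)

    def test_full_period_sinusoid_attenuated(self):
        # 0.5-Hz sinusoid at 10 Hz: the ±10-frame (21-sample ≈ one period)
        # window gain is |sin(21ω/2)/(21 sin(ω/2))| ≈ 0.047
        t = np.arange(400) / 10.0
        wave = np.sin(2 * np.pi * 0.5 * t)
        tr = make_track(wave, np.zeros_like(wave), rate_hz=10)
        sm = bh.smooth_track(tr, 10)
        interior = sm.x[50:-50]
        omega = 2 * np.pi * 0.5 / 10.0
        gain = abs(np.sin(21 * omega / 2) / (21 * np.sin(omega / 2)))
        assert np.max(np.abs(interior)) == pytest.approx(gain, rel=0.05)
        assert np.max(np.abs(interior)) < 0.05

    def test_resample_takes_every_tenth(self):
        tr = make_track(np.arange(100) * 0.01, np.zeros(100), rate_hz=10)
        r = bh.resample_1hz(tr)
        assert r.rate_hz == 1.0
        np.testing.assert_allclose(np.diff(r.time_s), 1.0)


class TestDetectTurns:
    def test_straight_track_has_no_turns(self):
        tr = make_track(np.arange(60) * 0.05, np.zeros(60))
        assert len(bh.detect_turns(tr).events) == 0

    def test_single_reversal_is_one_event(self):
        turns = bh.detect_turns(track_with_heading_change(180.0))
        assert len(turns.events) == 1

    @pytest.mark.parametrize("angle,expected", [(91.0, 1), (89.0, 0)])
    def test_threshold_boundary(self, angle, expected):
        turns = bh.detect_turns(track_with_heading_change(angle))
        assert len(turns.events) == expected

    def test_low_speed_extension_merges_following_seconds(self):
        # reversal followed by 3 near-stationary seconds joins one event
        step = 0.05
        x = list(np.arange(10) * step)
        y = [0.0] * 10
        for _ in range(3):
            x.append(x[-1] - 1e-4)
            y.append(0.0)
        for _ in range(10):
            x.append(x[-1] - step)
            y.append(0.0)
        turns = bh.detect_turns(make_track(x, y))
        assert len(turns.events) == 1
        s, e = turns.events[0]
        assert e - s >= 3.0

    def test_short_track_rejected(self):
        with pytest.raises(bh.BehaviorError):
            bh.detect_turns(make_track([0.0, 0.1], [0.0, 0.0]))


class TestIntervalMixture:
    def test_tcrit_recovered_from_synthetic_mixture(self):
        lam1, lam2 = 1 / 3.0, 1 / 30.0
        A1, A2 = 300.0, 30.0
        iv = syn.gen_turn_intervals(A1, lam1, A2, lam2, 20000, seed=5)
        fit = bh.fit_interval_mixture(iv)
        expected = np.log(A1 / A2) / (lam1 - lam2)
        assert fit.t_crit == pytest.approx(expected, rel=0.10)

    def test_lambda_recovery_at_n_1000(self):
        lam1, lam2 = 1 / 3.0, 1 / 30.0
        iv = syn.gen_turn_intervals(200.0, lam1, 20.0, lam2, 1000, seed=17)
        fit = bh.fit_interval_mixture(iv)
        assert fit.lam1 == pytest.approx(lam1, rel=0.15)
        assert fit.lam2 == pytest.approx(lam2, rel=0.15)

    def test_single_exponential_flags_degeneracy(self):
        rng = np.random.default_rng(3)
        iv = rng.exponential(5.0, 2000)
        with pytest.raises(bh.BehaviorError):
            bh.fit_interval_mixture(iv)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(bh.BehaviorError):
            bh.fit_interval_mixture(np.ones(10))


class TestSegmentStates:
    def _turns_from_intervals(self, gaps, turn_len=1.0):
        """Build a TurnSequence with the given inter-turn migratory gaps."""
        events = []
        t = 0.0
        for g in [0.0] + list(gaps):
            t += g
            events.append((t, t + turn_len))
            t += turn_len
        tmax = t
        times = np.arange(1.0, tmax + 1.0)
        flags = np.zeros(times.size, bool)
        return bh.TurnSequence(tuple(events), times, flags), tmax

    def test_example_intervals_give_one_run(self):
        turns, tmax = self._turns_from_intervals([5, 6, 20, 4])
        seg = bh.segment_states(turns, t_crit=13.1, window_s=(0.0, tmax))
        runs = seg.runs()
        assert len(runs) == 1
        assert runs[0][1] - runs[0][0] == pytest.approx(20.0)

    def test_no_turns_is_single_run(self):
        times = np.arange(1.0, 100.0)
        turns = bh.TurnSequence((), times, np.zeros(times.size, bool))
        seg = bh.segment_states(turns, 13.1, window_s=(0.0, 99.0))
        assert seg.intervals == ((0.0, 99.0, "run"),)

    def test_partition_covers_window_without_overlap(self):
        turns, tmax = self._turns_from_intervals([3, 15, 2, 40, 7])
        seg = bh.segment_states(turns, 13.1, window_s=(0.0, tmax))
        starts = [iv[0] for iv in seg.intervals]
        ends = [iv[1] for iv in seg.intervals]
        assert starts[0] == 0.0 and ends[-1] == tmax
        np.testing.assert_allclose(ends[:-1], starts[1:])

    def test_invalid_tcrit_rejected(self):
        turns, tmax = self._turns_from_intervals([5])
        with pytest.raises(bh.BehaviorError):
            bh.segment_states(turns, 0.0, window_s=(0.0, tmax))


class TestBearing:
    def test_down_gradient_is_zero(self):
        # at (2, 0) the gradient points toward the sources (−x), so moving
        # +x is down-gradient: B = 0 under the avoidance convention
        b = bh.bearing((1.0, 0.0), (2.0, 0.0), FIELD, 12.0, "away_zero")
        assert b == pytest.approx(0.0, abs=1.0)

    def test_up_gradient_is_180(self):
        b = bh.bearing((-1.0, 0.0), (2.0, 0.0), FIELD, 12.0, "away_zero")
        assert abs(b) == pytest.approx(180.0, abs=1.0)

    def test_perpendicular_is_90(self):
        b = bh.bearing((0.0, 1.0), (2.0, 0.0), FIELD, 12.0, "away_zero")
        assert abs(b) == pytest.approx(90.0, abs=1.0)

    def test_taxis_convention_flips_reference(self):
        b_away = bh.bearing((1.0, 0.3), (2.0, 0.0), FIELD, 12.0, "away_zero")
        b_toward = bh.bearing((1.0, 0.3), (2.0, 0.0), FIELD, 12.0, "toward_zero")
        assert abs(abs(b_away - b_toward)) % 360 == pytest.approx(180.0, abs=1e-6)

    def test_antiparallel_displacement_shifts_180(self):
        v = (0.7, -0.4)
        b1 = bh.bearing(v, (2.0, 0.5), FIELD, 12.0)
        b2 = bh.bearing((-v[0], -v[1]), (2.0, 0.5), FIELD, 12.0)
        assert (b2 - b1) % 360.0 == pytest.approx(180.0, abs=1e-9)

    def test_zero_displacement_rejected(self):
        with pytest.raises(bh.BehaviorError):
            bh.bearing((0.0, 0.0), (2.0, 0.0), FIELD)

    def test_rotation_invariance(self):
        # rotating displacement and the whole source frame together about the
        # position leaves the bearing unchanged
        pos = np.array([2.0, 0.0])
        v = np.array([0.6, 0.2])
        b0 = bh.bearing(v, pos, FIELD, 12.0)
        ang = np.radians(73.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rot_sources = tuple(tuple(pos + R @ (np.array(s) - pos))
                            for s in FIELD.sources)
        rot_field = of.GradientParams(sources=rot_sources)
        b1 = bh.bearing(R @ v, pos, rot_field, 12.0)
        assert b1 == pytest.approx(b0, abs=1e-6)


class TestFractionWithin90:
    def test_all_down_gradient_gives_one(self):
        assert bh.fraction_within_90(np.zeros(20)) == 1.0

    def test_boundary_counts_inward(self):
        assert bh.fraction_within_90([90.0, -90.0, 91.0]) == pytest.approx(2 / 3)

    def test_uniform_circle_gives_half(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(-180.0, 180.0, 200_000)
        assert bh.fraction_within_90(b) == pytest.approx(0.5, abs=0.01)


class TestTurningRateTimecourse:
    def test_single_turn_in_bin_rate(self):
        t = np.arange(1.0, 61.0)
        flags = np.zeros(60, bool)
        flags[14] = True  # one turn inside the second 10-s bin
        df = bh.turning_rate_timecourse([flags], t, bin_s=10.0)
        assert df["rate"].iloc[1] == pytest.approx(0.1)
        assert df["rate"].drop(index=1).sum() == 0.0

    def test_no_turns_all_zero(self):
        t = np.arange(1.0, 121.0)
        df = bh.turning_rate_timecourse([np.zeros(120, bool)] * 5, t)
        assert (df["rate"] == 0).all()

    def test_poisson_flags_mean_and_sem_scaling(self):
        rng = np.random.default_rng(8)
        t = np.arange(1.0, 601.0)
        for n in (10, 40):
            flags = rng.random((n, 600)) < 0.2
            df = bh.turning_rate_timecourse(list(flags), t)
            assert df["rate"].mean() == pytest.approx(0.2, abs=0.02)
        big = bh.turning_rate_timecourse(list(rng.random((80, 600)) < 0.2), t)
        small = bh.turning_rate_timecourse(list(rng.random((20, 600)) < 0.2), t)
        assert big["sem"].mean() == pytest.approx(small["sem"].mean() / 2,
                                                  rel=0.25)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(bh.BehaviorError):
            bh.turning_rate_timecourse([], np.arange(1.0, 10.0))


class TestTurningRateVsDcdt:
    def test_turns_only_after_positive_dcdt(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(-0.02, 0.02, 500)
        flags = np.zeros(500, bool)
        flags[1:] = d[:-1] > 0
        df = bh.turning_rate_vs_dcdt(d, flags)
        pos = df[df["bin_start"] >= 0.0]
        neg = df[df["bin_start"] < -0.005]
        assert (pos["p_turn"] == 1.0).all()
        assert (neg["p_turn"] == 0.0).all()

    def test_independent_turns_give_flat_profile(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(-0.02, 0.02, 20000)
        flags = rng.random(20000) < 0.1
        df = bh.turning_rate_vs_dcdt(d, flags)
        big = df[df["n"] > 500]
        assert np.allclose(big["p_turn"], 0.1, atol=0.03)

    def test_empty_state_empty_output(self):
        d = np.array([0.001, 0.002, 0.001])
        flags = np.array([False, True, False])
        df = bh.turning_rate_vs_dcdt(d, flags, states=["run", "run", "run"])
        assert set(df["state"]) == {"run"}


class TestPredictionInterval:
    def test_large_n_approaches_z_interval(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.1, 0.02, 100_000)
        pi = bh.prediction_interval(x, alpha=0.01)
        z = stats.norm.ppf(0.995)
        assert pi.upper == pytest.approx(pi.mean + z * pi.sd, rel=1e-3)

    def test_coverage_at_nominal_level(self):
        # empirical coverage of the 99% interval at n=20 over 1e5 draws
        rng = np.random.default_rng(12)
        n, reps = 20, 100_000
        samples = rng.normal(0.0, 1.0, (reps, n + 1))
        base, future = samples[:, :-1], samples[:, -1]
        mean = base.mean(axis=1)
        sd = base.std(axis=1, ddof=1)
        half = stats.t.ppf(0.995, n - 1) * sd * np.sqrt(1 + 1 / n)
        covered = np.abs(future - mean) <= half
        assert covered.mean() == pytest.approx(0.99, abs=0.005)
        # spot-check the vectorized oracle against the implementation
        pi = bh.prediction_interval(base[0], alpha=0.01)
        assert pi.upper == pytest.approx(mean[0] + half[0], rel=1e-12)

    def test_constant_baseline_zero_width(self):
        pi = bh.prediction_interval(np.full(10, 0.2), alpha=0.01)
        assert pi.lower == pi.upper == pytest.approx(0.2)

    def test_small_n_rejected(self):
        with pytest.raises(bh.BehaviorError):
            bh.prediction_interval([0.1], alpha=0.01)

    def test_first_crossing(self):
        rates = [0.1, 0.12, 0.3, 0.4]
        t = [0, 10, 20, 30]
        assert bh.first_crossing(t, rates, 0.2, "above") == 20.0
        assert bh.first_crossing(t, rates, 0.05, "below") is None


class TestQcFilter:
    def test_slow_track_excluded(self):
        t = np.arange(100.0)
        slow = make_track(t * 0.001 / 10.0, np.zeros(100))  # 0.01 mm/s
        kept, log = bh.qc_filter([{"track": slow}])
        assert kept == [] and log == [(0, "slow")]

    def test_normal_track_retained(self):
        t = np.arange(100.0)
        normal = make_track(t * 0.015, np.zeros(100))       # 0.15 mm/s
        kept, log = bh.qc_filter([{"track": normal}])
        assert len(kept) == 1 and log == []

    def test_all_four_reasons_logged(self):
        t = np.arange(100.0)
        records = [
            {"tracking_interrupted": True},
            {"basal_fluorescence": 5.0},
            {"abnormal_prestim_transient": True},
            {"track": make_track(t * 0.0005, np.zeros(100))},
        ]
        kept, log = bh.qc_filter(records, min_fluorescence=10.0)
        assert kept == []
        assert [r for _, r in log] == ["tracking_interrupted",
                                       "weak_fluorescence",
                                       "abnormal_prestim_transient", "slow"]

    def test_empty_input(self):
        assert bh.qc_filter([]) == ([], [])


class TestTrackIO:
    def test_round_trip(self, tmp_path):
        tracks = [make_track(np.arange(10) * 0.05, np.zeros(10))]
        path = tmp_path / "tracks.tsv"
        bh.write_tracks(tracks, path)
        back = bh.read_tracks(path)
        np.testing.assert_allclose(back[0].x, tracks[0].x)
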