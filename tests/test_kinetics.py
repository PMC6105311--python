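import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import minima_with_prominence_bruteforce
from tubemap import (
    SeriesError,
    SpotTrack,
    TrackPhantomSpec,
    analyze_track_pair,
    closing_speed,
    fill_gaps,
    find_cycle_minima,
    make_track_pair,
    pair_distance,
    smooth_distance,
    summarize_cycles,
    track_span,
)
from tubemap.kinetics import DistanceSeries, SpeedSeries


def _track(label, t, x, y=None):
    t = np.asarray(t, float)
    return SpotTrack(label=label, t=t, x=np.asarray(x, float),
                     y=np.zeros_like(t) if y is None else np.asarray(y, float))


class TestPairDistance:
    def test_static_pair(self):
        t = np.arange(0, 20, 2.0)
        a = _track("a", t, np.full(t.size, -5.0))
        p = _track("p", t, np.full(t.size, 5.0))
        series = pair_distance(a, p)
        np.testing.assert_allclose(series.d, 10.0)

    def test_gap_where_posterior_missing(self):
        t_a = np.arange(0, 12, 2.0)
        t_p = np.array([0.0, 2.0, 4.0, 6.0, 10.0])  # t=8 missing
        a = _track("a", t_a, np.zeros(t_a.size))
        p = _track("p", t_p, np.ones(t_p.size))
        series = pair_distance(a, p)
        assert 8.0 not in series.t
        np.testing.assert_array_equal(series.t, t_p)

    def test_pointwise_oracle(self, rng):
        t = np.arange(0, 40, 2.0)
        a = _track("a", t, rng.normal(size=t.size), rng.normal(size=t.size))
        p = _track("p", t, rng.normal(size=t.size), rng.normal(size=t.size))
        series = pair_distance(a, p)
        expected = [
            math.hypot(ax - px, ay - py)
            for ax, ay, px, py in zip(a.x, a.y, p.x, p.y)
        ]
        np.testing.assert_array_equal(series.d, expected)

    def test_no_common_timepoints(self):
        a = _track("a", [0.0, 2.0], [0, 0])
        p = _track("p", [1.0, 3.0], [1, 1])
        with pytest.raises(SeriesError):
            pair_distance(a, p)


class TestSmoothDistance:
    def test_constant_invariance(self):
        series = DistanceSeries(t=np.arange(0, 100, 2.0), d=np.full(50, 8.0), sampling_interval=2.0)
        out = smooth_distance(series)
        np.testing.assert_allclose(out.d, 8.0)

    def test_two_passes_equal_triangular_kernel_on_interior(self, rng):
        t = np.arange(0, 200, 2.0)
        d = 10 + rng.random(t.size)
        series = DistanceSeries(t=t, d=d, sampling_interval=2.0)
        out = smooth_distance(series, window=20.0, passes=2)
        box = np.ones(11) / 11
        tri = np.convolve(box, box)  # 21-tap triangle
        expected = np.convolve(d, tri, mode="same")
        interior = slice(10, t.size - 10)
        np.testing.assert_allclose(out.d[interior], expected[interior], rtol=1e-9)

    def test_sinusoid_attenuation_matches_oracle(self):
        t = np.arange(0, 400, 2.0)
        d = 20 + np.sin(2 * np.pi * t / 40.0)
        series = DistanceSeries(t=t, d=d, sampling_interval=2.0)
        out = smooth_distance(series, window=20.0, passes=2)
        box = np.ones(11) / 11
        tri = np.convolve(box, box)
        expected = np.convolve(d, tri, mode="same")
        interior = slice(10, t.size - 10)
        np.testing.assert_allclose(out.d[interior], expected[interior], rtol=1e-9)

    def test_window_smaller_than_interval_rejected(self):
        series = DistanceSeries(t=np.arange(0, 10, 2.0), d=np.ones(5), sampling_interval=2.0)
        with pytest.raises(SeriesError):
            smooth_distance(series, window=1.0)

    def test_smoothing_never_bridges_gaps(self):
        t = np.array([0, 2, 4, 20, 22, 24], dtype=float)
        d = np.array([1, 1, 1, 9, 9, 9], dtype=float)
        out = smooth_distance(DistanceSeries(t=t, d=d, sampling_interval=2.0))
        np.testing.assert_allclose(out.d[:3], 1.0)
        np.testing.assert_allclose(out.d[3:], 9.0)

    def test_shift_equivariance(self, rng):
        t = np.arange(0, 100, 2.0)
        d = 5 + rng.random(t.size)
        a = smooth_distance(DistanceSeries(t=t, d=d, sampling_interval=2.0))
        b = smooth_distance(DistanceSeries(t=t + 1000.0, d=d, sampling_interval=2.0))
        np.testing.assert_allclose(a.d, b.d)


class TestClosingSpeed:
    def test_linear_closing(self):
        t = np.arange(0, 100, 2.0)
        d = 20 - 0.1 * t
        v = closing_speed(DistanceSeries(t=t, d=d, sampling_interval=2.0))
        np.testing.assert_allclose(v.v, 0.1)

    def test_constant_distance(self):
        t = np.arange(0, 50, 2.0)
        v = closing_speed(DistanceSeries(t=t, d=np.full(t.size, 3.0), sampling_interval=2.0))
        np.testing.assert_allclose(v.v, 0.0)

    def test_analytic_derivative_bound(self):
        t = np.arange(0, 180, 2.0)  # keep d >= 0
        omega = 2 * np.pi / 40
        d = 10 - 0.05 * t - 0.5 * np.sin(omega * t)
        v = closing_speed(DistanceSeries(t=t, d=d, sampling_interval=2.0))
        analytic = 0.05 + 0.5 * omega * np.cos(omega * t)
        bound = omega**3 * 0.5 * 2.0**2 / 6  # |f'''| * dt^2 / 6
        interior = slice(1, -1)
        assert np.all(np.abs(v.v[interior] - analytic[interior]) <= bound + 1e-12)

    def test_all_runs_too_short(self):
        t = np.array([0.0, 2.0, 10.0, 12.0])
        with pytest.raises(SeriesError):
            closing_speed(DistanceSeries(t=t, d=np.ones(4), sampling_interval=2.0))


class TestFindCycleMinima:
    def _speed(self, t, v):
        return SpeedSeries(t=np.asarray(t, float), v=np.asarray(v, float), sampling_interval=2.0)

    def test_monotone_series_has_no_minima(self):
        t = np.arange(0, 40, 2.0)
        assert find_cycle_minima(self._speed(t, np.linspace(0, 1, t.size))).size == 0

    def test_sinusoid_minima_spacing(self):
        t = np.arange(0, 200, 2.0)
        v = -np.cos(2 * np.pi * t / 40.0)
        minima = find_cycle_minima(self._speed(t, v), prominence_threshold=0.01)
        # interior minima at t = 0 mod 40
        assert np.all(np.mod(minima, 40.0) <= 2.0) or np.all(np.mod(minima, 40.0) >= 38.0)
        spacing = np.diff(minima)
        assert np.all(np.abs(spacing - 40.0) <= 2.0)

    def test_exhaustive_prominence_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            v = np.round(rng.normal(size=n), 2)  # rounding provokes plateaus/ties
            thr = float(rng.uniform(0.005, 1.0))
            t = np.arange(n) * 2.0
            got = find_cycle_minima(self._speed(t, v), prominence_threshold=thr)
            expected_idx = minima_with_prominence_bruteforce(v, thr)
            np.testing.assert_array_equal(got, t[expected_idx])

    def test_plateau_resolved_to_first_sample(self):
        t = np.arange(0, 16, 2.0)
        v = np.array([3.0, 1.0, 1.0, 1.0, 3.0, 3.0, 3.0, 3.0])
        minima = find_cycle_minima(self._speed(t, v), prominence_threshold=0.5)
        np.testing.assert_array_equal(minima, [2.0])

    def test_run_edges_excluded(self):
        # v dips right at the start of the second run: not an interior minimum
        t = np.array([0, 2, 4, 100, 102, 104], dtype=float)
        v = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 2.0])
        minima = find_cycle_minima(self._speed(t, v), prominence_threshold=0.5)
        np.testing.assert_array_equal(minima, [2.0])

    def test_nonpositive_threshold_rejected(self):
        t = np.arange(0, 10, 2.0)
        with pytest.raises(SeriesError):
            find_cycle_minima(self._speed(t, np.zeros(5)), prominence_threshold=0.0)


class TestSummarizeCycles:
    def test_arithmetic(self):
        s = summarize_cycles(np.array([10.0, 50.0, 90.0]))
        np.testing.assert_array_equal(s.cycle_durations, [40.0, 40.0])
        assert s.mean_period == 40.0
        assert s.sem_period == 0.0
        assert s.n_cycles == 2

    def test_single_minimum(self):
        s = summarize_cycles(np.array([10.0]))
        assert s.cycle_durations.size == 0
        assert math.isnan(s.mean_period)

    def test_empty(self):
        s = summarize_cycles(np.array([]))
        assert s.n_cycles == 0


class TestTrackSpan:
    def test_arithmetic(self):
        tr = _track("a", [0, 2, 4], [3.2, 7.8, 5.0])
        assert track_span(tr) == pytest.approx(4.6)

    def test_single_point(self):
        assert track_span(_track("a", [0.0], [1.0])) == 0.0

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_max_minus_min_oracle(self, xs):
        t = np.arange(len(xs), dtype=float)
        tr = _track("a", t, xs)
        assert track_span(tr) == max(xs) - min(xs)


class TestPipelineRecovery:
    @pytest.mark.parametrize("period,amplitude", [(30.0, 0.9), (40.0, 0.5), (60.0, 0.6)])
    def test_planted_period_recovery(self, period, amplitude):
        recovered = []
        for seed in range(10):
            spec = TrackPhantomSpec(
                duration=12 * period,
                initial_distance=40.0,
                phases=[("contraction", 12 * period, 0.03)],
                oscillation_amplitude=amplitude,
                period=period,
                positional_noise_sigma=0.02,
                seed=seed,
            )
            anterior, posterior, truth = make_track_pair(spec)
            res = analyze_track_pair(anterior, posterior)
            recovered.append(res["summary"].mean_period)
        assert abs(np.median(recovered) - period) <= 2.0

    def test_recovery_with_dropout_interpolating(self):
        # strict gap splitting cannot meet this (see ledger); interpolate can
        recovered = []
        for seed in range(10):
            spec = TrackPhantomSpec(
                duration=600.0,
                initial_distance=50.0,
                phases=[("contraction", 600.0, 0.03)],
                oscillation_amplitude=0.5,
                period=40.0,
                positional_noise_sigma=0.02,
                dropout_probability=0.10,
                seed=seed,
            )
            anterior, posterior, truth = make_track_pair(spec)
            res = analyze_track_pair(anterior, posterior, gap_policy="interpolate")
            recovered.append(res["summary"].mean_period)
        assert abs(np.median(recovered) - 40.0) <= 2.0

    def test_zero_amplitude_zero_cycles(self):
        spec = TrackPhantomSpec(
            duration=300.0,
            initial_distance=30.0,
            phases=[("contraction", 300.0, 0.05)],
            oscillation_amplitude=0.0,
            period=40.0,
            seed=0,
        )
        anterior, posterior, truth = make_track_pair(spec)
        res = analyze_track_pair(anterior, posterior)
        assert res["summary"].n_cycles == 0
        assert truth.minima_times.size == 0

    def test_fill_gaps_restores_grid(self):
        t = np.array([0, 2, 4, 8, 10], dtype=float)
        d = np.array([1, 2, 3, 5, 6], dtype=float)
        filled = fill_gaps(DistanceSeries(t=t, d=d, sampling_interval=2.0))
        np.testing.assert_array_equal(filled.t, [0, 2, 4, 6, 8, 10])
        assert filled.d[3] == pytest.approx(4.0)
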