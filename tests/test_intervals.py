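"""Interval statistics, histograms, nonlinear fits, and the width trend."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from antegress import (
    ConfigurationError,
    DomainError,
    DEFAULT_BETA_BY_WIDTH,
    EgressSeries,
    IntervalSet,
    ValidationError,
    beta_trend,
    build_histogram,
    compute_intervals,
    fit_escape_curve,
    fit_exp_decay,
    fit_interval_frequency,
    fit_sat_exp,
    mean_flow_rate,
    mean_interval,
    pool_intervals,
)


def iset(values, width=0.5, condition="repellent", source="per_trial"):
    return IntervalSet(width, condition, np.array(values, dtype=float), source)


def series(times, width=0.5):
    return EgressSeries("s", "repellent", width, max(len(times), 1) + 2, np.array(times))


class TestComputeIntervals:
    @pytest.mark.parametrize(
        "times, expected",
        [
            ([0.0, 1.2, 3.0], [1.2, 1.8]),
            ([0.0], []),
            ([], []),
            ([0.0, 0.0, 2.0], [0.0, 2.0]),  # simultaneous escapes give a zero interval
        ],
    )
    def test_successive_differences(self, times, expected):
        np.testing.assert_allclose(compute_intervals(series(times)).intervals_s, expected)

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=30))
    def test_cumsum_reconstructs_times(self, gaps):
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        iv = compute_intervals(series(list(times))).intervals_s
        np.testing.assert_allclose(np.concatenate([[0.0], np.cumsum(iv)]), times, atol=1e-9)


class TestPooling:
    def test_concatenation(self):
        pooled = pool_intervals([iset([1, 2]), iset([3])], width=0.5)
        np.testing.assert_allclose(pooled.intervals_s, [1, 2, 3])
        assert pooled.source == "pooled"

    def test_single_set_identity(self):
        pooled = pool_intervals([iset([1, 2])])
        np.testing.assert_allclose(pooled.intervals_s, [1, 2])

    def test_mixed_widths_rejected(self):
        with pytest.raises(ValidationError, match="width"):
            pool_intervals([iset([1], width=0.5), iset([2], width=1.0)])

    def test_mixed_conditions_rejected(self):
        with pytest.raises(ValidationError, match="condition"):
            pool_intervals([iset([1]), iset([2], condition="control")])


class TestMeans:
    def test_mean_interval(self):
        assert mean_interval(iset([1, 2, 3])) == pytest.approx(2.0)

    def test_mean_of_empty_set_is_error(self):
        with pytest.raises(DomainError):
            mean_interval(iset([]))

    def test_flow_rate_is_reciprocal(self):
        assert mean_flow_rate(iset([2.0, 2.0])) == pytest.approx(0.5)
        # reciprocal of the characteristic 0.5 cm mean interval
        assert mean_flow_rate(iset([5.66])) == pytest.approx(0.1767, abs=1e-4)

    def test_all_simultaneous_flow_undefined(self):
        with pytest.raises(DomainError):
            mean_flow_rate(iset([0.0, 0.0]))

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=50))
    def test_q_times_mean_is_one(self, values):
        s = iset(values)
        assert mean_flow_rate(s) * mean_interval(s) == pytest.approx(1.0, abs=1e-12)


class TestHistogram:
    def test_sturges_bin_count(self):
        h = build_histogram(iset(list(range(1, 9))))  # 8 values -> ceil(1+log2 8) = 4
        assert h.counts.size == 4
        assert h.rule == "sturges"

    def test_single_value_one_bin(self):
        h = build_histogram(iset([2.5]))
        assert h.counts.size == 1
        assert h.counts[0] == 1

    @given(st.lists(st.floats(0.0, 50.0), min_size=1, max_size=200))
    def test_counts_partition_data(self, values):
        h = build_histogram(iset(values))
        assert int(h.counts.sum()) == len(values)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.exponential(2.0, 64)
        h1 = build_histogram(iset(list(values)))
        h2 = build_histogram(iset(list(rng.permutation(values))))
        np.testing.assert_array_equal(h1.counts, h2.counts)
        np.testing.assert_allclose(h1.bin_edges_s, h2.bin_edges_s)

    def test_fixed_width_requires_width(self):
        with pytest.raises(ConfigurationError):
            build_histogram(iset([1, 2, 3]), rule="fixed_width")

    def test_fixed_width_bins(self):
        h = build_histogram(iset([0.2, 1.4, 2.9]), rule="fixed_width", fixed_width_s=1.0)
        assert h.counts.size == 3
        assert int(h.counts.sum()) == 3

    def test_empty_set_rejected(self):
        with pytest.raises(DomainError):
            build_histogram(iset([]))


class TestExpDecayFit:
    def test_exact_model_data_recovered(self):
        x = np.linspace(0.2, 12.0, 10)
        y = 10.0 * np.exp(-x / 3.0) + 0.5
        fit = fit_exp_decay(x, y)
        assert fit.converged
        assert fit.alpha == pytest.approx(10.0, rel=1e-6)
        assert fit.beta == pytest.approx(3.0, rel=1e-6)
        assert fit.epsilon == pytest.approx(0.5, rel=1e-6)

    def test_fewer_than_three_bins_rejected(self):
        h = build_histogram(iset([1.0, 1.1]))  # 2 values -> 2 sturges bins
        with pytest.raises(DomainError):
            fit_interval_frequency(h)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_oracle(self, seed):
        """The least-squares optimum beats every point of a 100^3 brute-force
        lattice around the moment start, and sits within one lattice step of
        the lattice optimum whenever it falls inside the searched box."""
        rng = np.random.default_rng(seed)
        values = rng.exponential(rng.uniform(1.0, 4.0), 40)
        h = build_histogram(iset(list(values)))
        fit = fit_interval_frequency(h)
        a, b, e, sse, steps, box = oracles.grid_search_exp_decay(h.midpoints_s, h.frequencies)
        assert fit.sse <= sse + 1e-12
        inside = all(lo <= v <= hi for v, (lo, hi)
                     in zip((fit.alpha, fit.beta, fit.epsilon), box))
        if inside:
            # flat SSE valleys can park the lattice optimum one cell over
            assert abs(fit.beta - b) <= 2 * steps[1] + 1e-12

    def test_recovers_beta_from_large_sample(self):
        rng = np.random.default_rng(42)
        h = build_histogram(iset(list(rng.exponential(2.5, 20_000))))
        fit = fit_interval_frequency(h)
        assert fit.converged
        assert fit.beta == pytest.approx(2.5, rel=0.05)


class TestEscapeCurveFit:
    def test_exact_model_data_recovered(self):
        x = np.linspace(0.0, 30.0, 12)
        y = 30.0 - 30.0 * np.exp(-x / 5.0)
        fit = fit_sat_exp(x, y)
        assert fit.converged
        assert fit.y0 == pytest.approx(30.0, rel=1e-6)
        assert fit.A1 == pytest.approx(-30.0, rel=1e-6)
        assert fit.t1 == pytest.approx(5.0, rel=1e-6)

    def test_series_on_model_curve(self):
        """Event times on y = 30 - 30 exp(-t/5); re-referencing to time zero
        folds the shift into the amplitude but leaves y0 and t1 intact."""
        i = np.arange(1, 25)
        t = -5.0 * np.log(1 - i / 30.0)
        shift = t[0]
        s = EgressSeries("m", "repellent", 1.0, 30, t - shift)
        fit = fit_escape_curve(s)
        assert fit.converged
        assert fit.y0 == pytest.approx(30.0, rel=1e-6)
        assert fit.t1 == pytest.approx(5.0, rel=1e-6)
        assert fit.A1 == pytest.approx(-30.0 * np.exp(-shift / 5.0), rel=1e-6)

    def test_asymptote_tracks_total_count(self):
        """For a saturating escape process (each remaining ant leaves at a
        fixed per-capita rate, so gaps lengthen as the chamber empties) the
        fitted plateau is close to the number that actually escaped
        (oracle: the final count)."""
        rng = np.random.default_rng(0)
        n, lam = 60, 0.5
        gaps = [rng.exponential(1.0 / ((n - i) * lam)) for i in range(1, n)]
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        s = EgressSeries("n", "repellent", 1.0, n, times)
        fit = fit_escape_curve(s)
        assert fit.converged
        assert fit.y0 == pytest.approx(n, rel=0.15)

    def test_too_few_events_rejected(self):
        with pytest.raises(DomainError):
            fit_escape_curve(series([0.0, 1.0, 2.0]))


class TestBetaTrend:
    def test_collinear_points_exact(self):
        fit = beta_trend([(0.5, 3.0), (1.0, 2.5), (1.5, 2.0)])
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(3.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_characteristic_betas_decrease_with_width(self):
        """The six width-specific decay scales slope downward."""
        fit = beta_trend(sorted(DEFAULT_BETA_BY_WIDTH.items()))
        assert fit.slope < 0

    def test_single_width_rejected(self):
        with pytest.raises(DomainError):
            beta_trend([(0.5, 3.0), (0.5, 2.0)])
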