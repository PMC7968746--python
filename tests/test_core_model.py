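import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import fpinfer as fp
from fpinfer.core_model import InvalidInputError, InvalidParameterError


class TestPathDensity:
    def test_exponential_special_case(self):
        assert fp.path_density(1.0, tau=1.0, L=1.0) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_normalizes_to_one(self):
        val, _ = integrate.quad(lambda t: fp.path_density(t, 2.0, 3.5), 0, 200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_mode_at_L_minus_one_tau(self):
        # Erlang mode (L-1)*tau = 6 for tau=2, L=4
        grid = np.linspace(0.01, 30, 20000)
        assert grid[np.argmax(fp.path_density(grid, 2.0, 4.0))] == pytest.approx(6.0, abs=0.01)

    @pytest.mark.parametrize("tau,L", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_rejects_nonpositive_parameters(self, tau, L):
        with pytest.raises(InvalidParameterError):
            fp.path_density(1.0, tau, L)

    def test_rejects_negative_time(self):
        with pytest.raises(InvalidInputError):
            fp.path_density(-0.5, 1.0, 1.0)

    def test_log_density_stable_at_large_shape(self):
        # L = 100 would overflow factorials in linear arithmetic
        val = fp.path_log_density(100.0, tau=1.0, L=100.0)
        assert np.isfinite(val)


class TestPathCDF:
    def test_zero_at_origin(self):
        assert fp.path_cdf(0.0, 3.0, 2.5) == 0.0

    def test_exponential_median(self):
        tau = 4.0
        assert fp.path_cdf(tau * np.log(2), tau, 1.0) == pytest.approx(0.5, rel=1e-12)

    def test_matches_quadrature_of_density(self):
        val, _ = integrate.quad(lambda t: fp.path_density(t, 1.0, 3.0), 0, 5)
        assert fp.path_cdf(5.0, 1.0, 3.0) == pytest.approx(val, abs=1e-9)

    def test_monotone_and_saturating(self):
        grid = np.linspace(0, 500, 400)
        c = fp.path_cdf(grid, 2.0, 5.0)
        assert np.all(np.diff(c) >= 0)
        assert c[-1] == pytest.approx(1.0, abs=1e-10)


class TestMixtureWeights:
    @pytest.mark.parametrize(
        "x,expected",
        [([], [1.0]), ([1.0, 1.0], [1 / 3, 1 / 3, 1 / 3]), ([3.0], [0.25, 0.75])],
    )
    def test_flux_to_probability(self, x, expected):
        np.testing.assert_allclose(fp.mixture_weights(x), expected, rtol=1e-12)

    @given(st.lists(st.floats(0, 1e3), min_size=0, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_always_a_probability_vector(self, x):
        p = fp.mixture_weights(x)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rejects_negative_flux(self):
        with pytest.raises(InvalidParameterError):
            fp.mixture_weights([-0.1])


class TestMixtureDensity:
    def test_single_path_reduces_to_path_density(self):
        m = fp.FPModel(tau=[2.0], L=[3.0])
        grid = np.linspace(0.1, 30, 50)
        np.testing.assert_allclose(
            fp.mixture_density(grid, m), fp.path_density(grid, 2.0, 3.0), rtol=1e-14
        )

    def test_zero_flux_path_is_invisible(self):
        # nestedness: appending a path with x=0 changes nothing
        m2 = fp.FPModel(tau=[2.0, 9.0], L=[3.0, 1.5], x=[0.0])
        m1 = fp.FPModel(tau=[2.0], L=[3.0])
        grid = np.linspace(0.0, 60, 200)
        np.testing.assert_allclose(
            fp.mixture_density(grid, m2), fp.mixture_density(grid, m1), atol=1e-12
        )

    def test_normalization_over_wide_window(self, two_path_model):
        tbar_max = float(np.max(two_path_model.tau * two_path_model.L))
        val, _ = integrate.quad(
            lambda t: fp.mixture_density(t, two_path_model), 0, 50 * tbar_max, limit=200
        )
        assert val >= 0.999

    def test_sample_mean_matches_mixture_mean(self):
        m = fp.FPModel(tau=[2.0, 10.0], L=[5.0, 5.0], x=[1.0])  # T-bar 10, 50; p=1/2
        t = fp.sample_fp_times(m, 100_000, seed=11)
        expected_mean = 30.0
        expected_var = 0.5 * (10**2 / 5 + 50**2 / 5) + 0.5 * (10 - 30) ** 2 + 0.5 * (50 - 30) ** 2
        se = np.sqrt(expected_var / t.size)
        assert abs(t.mean() - expected_mean) < 3 * se


class TestBinProbability:
    def test_partition_telescopes_to_cdf(self, two_path_model):
        edges = np.linspace(0, 120, 241)
        probs = fp.bin_probabilities(edges, two_path_model)
        assert probs.sum() == pytest.approx(fp.mixture_cdf(120.0, two_path_model), abs=1e-10)

    def test_exponential_closed_form(self):
        m = fp.FPModel(tau=[7.0], L=[1.0])
        lo, hi = 2.0, 5.0
        expected = np.exp(-lo / 7.0) - np.exp(-hi / 7.0)
        assert fp.bin_probability(lo, hi, m) == pytest.approx(expected, rel=1e-12)

    def test_midpoint_error_is_second_order_in_dt(self, two_path_model):
        center = 12.0
        errs = []
        for dt in (0.8, 0.4, 0.2):
            exact = fp.bin_probability(center - dt / 2, center + dt / 2, two_path_model)
            mid = fp.bin_probability(center - dt / 2, center + dt / 2, two_path_model, "midpoint")
            errs.append(abs(exact - mid) / dt)  # per-unit-width error
        # halving dt should shrink the per-width error ~4x (O(dt^2) overall)
        assert errs[1] / errs[0] < 0.35
        assert errs[2] / errs[1] < 0.35

    def test_rejects_inverted_bin(self, two_path_model):
        with pytest.raises(InvalidInputError):
            fp.bin_probability(5.0, 5.0, two_path_model)


class TestSampling:
    def test_identical_seed_identical_sample(self, two_path_model):
        a = fp.sample_fp_times(two_path_model, 1000, seed=5)
        b = fp.sample_fp_times(two_path_model, 1000, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_rejects_empty_request(self, two_path_model):
        with pytest.raises(InvalidInputError):
            fp.sample_fp_times(two_path_model, 0, seed=1)

    def test_path_choice_frequencies(self):
        m = fp.FPModel(tau=[1.0, 100.0], L=[1.0, 25.0], x=[0.25])  # p = (0.8, 0.2)
        t = fp.sample_fp_times(m, 100_000, seed=13)
        # the two paths barely overlap; classify by threshold at 20 ms
        frac_slow = np.mean(t > 20)
        assert abs(frac_slow - 0.2) < 3 * np.sqrt(0.2 * 0.8 / t.size)

    def test_single_path_cv(self):
        t = fp.sample_fp_times(fp.FPModel(tau=[2.0], L=[4.0]), 100_000, seed=17)
        cv = t.std() / t.mean()
        assert cv == pytest.approx(0.5, abs=0.01)


class TestPathSummaries:
    def test_values_and_weight_sum(self):
        m = fp.FPModel(tau=[2.0], L=[8.0])
        (s,) = fp.path_summaries(m)
        assert s.mean_completion == pytest.approx(16.0)
        assert s.cv == pytest.approx(1 / np.sqrt(8), rel=1e-12)
        assert s.weight == 1.0

    def test_round_trip_through_summaries(self, two_path_model):
        rebuilt = fp.model_from_summaries(fp.path_summaries(two_path_model))
        np.testing.assert_allclose(rebuilt.tau, two_path_model.tau, rtol=1e-10)
        np.testing.assert_allclose(rebuilt.L, two_path_model.L, rtol=1e-10)
        np.testing.assert_allclose(rebuilt.x, two_path_model.x, rtol=1e-10)

    def test_theta_round_trip(self, two_path_model):
        np.testing.assert_array_equal(
            fp.FPModel.from_theta(two_path_model.theta).theta, two_path_model.theta
        )
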