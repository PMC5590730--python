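import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import chi2, norm

from metapower import (
    EffectScenario,
    EqualSizeScenario,
    InsufficientStudiesError,
    MCConfig,
    MetaAnalysisData,
    TestSpec,
    ValidationError,
    gamma1,
    map_to_equal_size,
    power_grid,
    power_k1_meta,
    power_k1_study,
    power_no_uncertainty,
    power_re_analytic,
    power_re_equal,
    power_re_mc,
    simulate_t_stats,
    study_power,
    study_powers_random,
    t_cdf_equal,
    typical_variance,
)


class TestGamma1:
    def test_zero_at_origin(self):
        for a in (0.5, 1.0, 3.7):
            assert gamma1(a, 0.0) == 0.0

    def test_exponential_closed_form(self):
        # a = 1: regularised and unnormalised forms coincide, 1 - exp(-x)
        for x in (0.1, 1.0, 5.0):
            assert gamma1(1.0, x) == pytest.approx(1 - math.exp(-x), rel=1e-12)

    @pytest.mark.parametrize("k, i2", [(3, 0.0), (5, 0.25), (10, 0.9), (50, 0.5)])
    def test_equals_truncation_probability(self, k, i2):
        """gamma1((k-1)/2, (1-I2)(k-1)/2) is Pr(chi2_{k-1} <= (1-I2)(k-1)),
        the probability that the DL estimate truncates to zero."""
        val = gamma1((k - 1) / 2, (1 - i2) * (k - 1) / 2)
        assert val == pytest.approx(chi2.cdf((1 - i2) * (k - 1), k - 1), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            gamma1(0.0, 1.0)
        with pytest.raises(ValidationError):
            gamma1(1.0, -0.1)


def _cdf_quad_reference(t: float, k: int, i2: float, delta_nc: float) -> float:
    """Scalar adaptive-quadrature reference for the mixture CDF of T."""
    df = k - 1
    s = math.sqrt(1 - i2)
    lead = chi2.cdf((1 - i2) * df, df) * norm.cdf((t - delta_nc) * s)

    def integrand(x):
        return 2 * df * x * norm.cdf(t * x - delta_nc * s) * chi2.pdf(df * x**2, df)

    val, _ = integrate.quad(integrand, s, np.inf, limit=200)
    return lead + val


class TestTCdfEqual:
    @pytest.mark.parametrize("k, i2, delta_nc", [(2, 0.5, 1.0), (5, 0.9, 0.0), (10, 0.25, 3.0)])
    def test_matches_adaptive_quadrature(self, k, i2, delta_nc):
        sc = EqualSizeScenario(k=k, i2=i2, delta_nc=delta_nc)
        for t in (-2.0, 0.0, 1.96, 4.0):
            assert t_cdf_equal(t, sc) == pytest.approx(
                _cdf_quad_reference(t, k, i2, delta_nc), abs=1e-7
            )

    def test_is_a_proper_cdf(self):
        sc = EqualSizeScenario(k=4, i2=0.6, delta_nc=1.5)
        grid = np.linspace(-12, 12, 401)
        f = t_cdf_equal(grid, sc)
        assert np.all(np.diff(f) >= -1e-12)
        assert f[0] == pytest.approx(0.0, abs=1e-8)
        assert f[-1] == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_about_zero_when_centred(self):
        sc = EqualSizeScenario(k=6, i2=0.4, delta_nc=0.0)
        assert t_cdf_equal(0.0, sc) == pytest.approx(0.5, abs=1e-10)
        assert t_cdf_equal(1.3, sc) + t_cdf_equal(-1.3, sc) == pytest.approx(1.0, abs=1e-9)

    def test_matches_simulated_t_distribution(self):
        """MC oracle: the CDF agrees with the empirical distribution of the
        simulated DL test statistic for equal-size studies."""
        k, i2, delta_nc = 5, 0.5, 1.0
        sigma = 1.0
        tau2 = i2 * sigma**2 / (1 - i2)
        delta = delta_nc * sigma / math.sqrt(k)
        t = simulate_t_stats(
            np.full(k, sigma), EffectScenario(delta=delta, tau2=tau2), MCConfig(100_000, 13)
        )
        sc = EqualSizeScenario(k=k, i2=i2, delta_nc=delta_nc)
        grid = np.quantile(t, np.linspace(0.002, 0.998, 499))
        emp = np.searchsorted(np.sort(t), grid, side="right") / t.size
        assert np.max(np.abs(t_cdf_equal(grid, sc) - emp)) < 0.006

    def test_large_k_low_heterogeneity_is_shifted_normal(self):
        # convergence is O(1/sqrt(k)) in the tails, so probe the limit at large k
        sc = EqualSizeScenario(k=20_000, i2=1e-9, delta_nc=1.2)
        for t in (-1.0, 0.5, 2.0):
            assert t_cdf_equal(t, sc) == pytest.approx(norm.cdf(t - 1.2), abs=2e-3)

    def test_i2_one_rejected(self):
        with pytest.raises(ValidationError):
            EqualSizeScenario(k=3, i2=1.0, delta_nc=1.0)


class TestPowerREEqual:
    def test_invariant_under_sign_of_delta(self, spec):
        p_pos = power_re_equal(EqualSizeScenario(k=5, i2=0.3, delta_nc=2.0), spec).power
        p_neg = power_re_equal(EqualSizeScenario(k=5, i2=0.3, delta_nc=-2.0), spec).power
        assert p_pos == pytest.approx(p_neg, abs=1e-10)

    def test_matches_mc_power(self, spec):
        k, i2, delta_nc = 3, 0.25, 2.0
        tau2 = i2 / (1 - i2)
        p_eq = power_re_equal(EqualSizeScenario(k=k, i2=i2, delta_nc=delta_nc), spec).power
        p_mc = power_re_mc(
            np.ones(k),
            EffectScenario(delta=delta_nc / math.sqrt(k), tau2=tau2),
            spec,
            MCConfig(100_000, 19),
        )
        assert abs(p_eq - p_mc.power) < 3 * p_mc.mc_se

    def test_anticonservative_at_small_k_severe_heterogeneity(self, spec):
        """The conventional DL test rejects far more than alpha when k is tiny
        and heterogeneity severe, so the mixture power exceeds the
        no-uncertainty value markedly."""
        p_mix = power_re_equal(EqualSizeScenario(k=3, i2=0.9, delta_nc=0.5), spec).power
        p_nou = power_no_uncertainty(0.5, 0.9, spec).power
        assert p_mix > p_nou + 0.02

    def test_large_k_converges_to_no_uncertainty(self, spec):
        for i2, d in [(0.0, 1.0), (0.5, 2.0), (0.9, 3.0)]:
            p_mix = power_re_equal(EqualSizeScenario(k=1000, i2=i2, delta_nc=d), spec).power
            p_nou = power_no_uncertainty(d, i2, spec).power
            assert abs(p_mix - p_nou) < 0.005


class TestPowerNoUncertainty:
    def test_null_gives_alpha(self, spec):
        assert power_no_uncertainty(0.0, 0.3, spec).power == pytest.approx(spec.alpha, abs=1e-9)

    def test_total_heterogeneity_gives_alpha(self, spec):
        assert power_no_uncertainty(4.0, 1.0, spec).power == pytest.approx(spec.alpha, abs=1e-9)

    def test_frozen_value(self, spec):
        # Phi(2.8016 - 1.96) = 0.800 plus a negligible lower tail
        assert power_no_uncertainty(2.8016, 0.0, spec).power == pytest.approx(0.79999, abs=1e-4)

    def test_decreasing_in_i2(self, spec):
        powers = [power_no_uncertainty(2.0, i2, spec).power for i2 in (0.0, 0.25, 0.5, 0.75, 0.95)]
        assert np.all(np.diff(powers) < 0)

    def test_equals_analytic_on_equal_studies(self, spec):
        """V_R = (sigma^2 + tau2)/k makes the no-uncertainty formula an exact
        reparameterisation of the conventional analytic power."""
        k, sigma, tau2, delta = 7, 0.8, 0.3, 0.35
        i2 = tau2 / (sigma**2 + tau2)
        delta_nc = delta * math.sqrt(k) / sigma
        p1 = power_no_uncertainty(delta_nc, i2, spec).power
        p2 = power_re_analytic(
            np.full(k, sigma), EffectScenario(delta=delta, tau2=tau2), spec
        ).power
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestK1Comparison:
    def test_equal_at_tau2_zero(self, spec):
        for d, s in [(0.0, 1.0), (0.7, 0.4), (2.0, 1.3)]:
            assert power_k1_study(d, s, 0.0, spec).power == pytest.approx(
                power_k1_meta(d, s, 0.0, spec).power, abs=1e-14
            )
            assert power_k1_meta(d, s, 0.0, spec).power == pytest.approx(
                study_power(d, s, spec).power, abs=1e-14
            )

    def test_study_exceeds_meta_under_heterogeneity(self, spec):
        for d in (0.0, 0.5, 1.5):
            for tau2 in (0.1, 0.5, 2.0):
                assert (
                    power_k1_study(d, 1.0, tau2, spec).power
                    > power_k1_meta(d, 1.0, tau2, spec).power
                )

    def test_study_null_exceeds_alpha_under_heterogeneity(self, spec):
        assert power_k1_study(0.0, 1.0, 0.5, spec).power > spec.alpha

    def test_meta_frozen_value(self, spec):
        expected = 0.1089476530  # 1 + Phi(-1.96 + 1/sqrt 2) - Phi(1.96 + 1/sqrt 2)
        assert power_k1_meta(1.0, 1.0, 1.0, spec).power == pytest.approx(expected, abs=1e-9)

    def test_study_matches_per_study_random_power(self, spec):
        data = MetaAnalysisData.from_arrays([0.0], [0.6])
        vec = study_powers_random(data, EffectScenario(delta=0.9, tau2=0.4), spec)
        assert power_k1_study(0.9, 0.6, 0.4, spec).power == pytest.approx(vec.powers[0], abs=1e-12)


class TestTypicalVariance:
    def test_equal_sigmas_recovered_by_both_methods(self):
        data = MetaAnalysisData.from_arrays([0, 0, 0], [0.7, 0.7, 0.7])
        for method in ("higgins_thompson", "mean_precision_reciprocal"):
            assert typical_variance(data, method).value == pytest.approx(0.49, rel=1e-12)

    def test_hand_values(self):
        data = MetaAnalysisData.from_arrays([0, 0], [1.0, math.sqrt(2)])
        assert typical_variance(data, "higgins_thompson").value == pytest.approx(1.5)
        assert typical_variance(data, "mean_precision_reciprocal").value == pytest.approx(4 / 3)

    def test_higgins_thompson_needs_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            typical_variance(MetaAnalysisData.from_arrays([0.0], [1.0]), "higgins_thompson")


class TestMapToEqualSize:
    def test_equal_sigma_round_trip(self):
        k, sigma = 4, 0.5
        data = MetaAnalysisData.from_arrays([0] * k, [sigma] * k)
        sc = map_to_equal_size(data, delta=0.3, tau2=0.25)
        assert sc.k == k
        assert sc.i2 == pytest.approx(0.25 / (0.25 + sigma**2))
        assert sc.delta_nc == pytest.approx(0.3 * 2 / sigma)

    def test_tau2_zero_maps_to_i2_zero(self, mixed_sigma_data):
        assert map_to_equal_size(mixed_sigma_data, delta=0.2, tau2=0.0).i2 == 0.0

    def test_hand_example(self):
        data = MetaAnalysisData.from_arrays([0, 0], [1.0, math.sqrt(2)])
        sc = map_to_equal_size(data, delta=0.5, tau2=1.5, method="higgins_thompson")
        assert sc.i2 == pytest.approx(0.5)


class TestPowerGrid:
    def test_no_uncertainty_null_row_is_alpha(self, spec):
        grid = power_grid(5, [0.0, 1.0, 2.0], [0.0, 0.5], spec, method="no_uncertainty")
        np.testing.assert_allclose(grid[0], spec.alpha, atol=1e-9)
        assert grid.shape == (3, 2)

    def test_no_uncertainty_rows_increase_in_delta(self, spec):
        grid = power_grid(5, [0.0, 0.5, 1.0, 2.0, 4.0], [0.0, 0.3, 0.8], spec, method="no_uncertainty")
        assert np.all(np.diff(grid, axis=0) > 0)

    def test_mixture_exceeds_no_uncertainty_at_small_k_large_i2(self, spec):
        deltas, i2s = [0.2, 0.5], [0.9, 0.95]
        mix = power_grid(3, deltas, i2s, spec, method="mixture")
        nou = power_grid(3, deltas, i2s, spec, method="no_uncertainty")
        assert np.all(mix > nou)

    def test_unsorted_grid_rejected(self, spec):
        with pytest.raises(ValidationError):
            power_grid(3, [1.0, 0.5], [0.0], spec)
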