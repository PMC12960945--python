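"""The macroscopic constant-speed model against its stated oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from rangesweep.analytic import (
    MacroParams,
    REFINED_1D_Y2_COEFF,
    arrival_time_density,
    cancer_speed_estimate,
    conditional_sweep_prob,
    location_density,
    location_density_conditional,
    location_moments,
    posterior_radius_given_sweep,
    radius_density,
    radius_moments,
    scales,
    sweep_probability,
    sweep_probability_from_rates,
)
from rangesweep.poisson import cumulative_intensity
from rangesweep._geometry import UNIT_BALL_VOLUME


class TestScales:
    def test_printed_3d_theta(self, params3d):
        # theta = (3 c_wt / (pi mu))^(1/4) ~ 15.8 at the defaults
        sc = scales(params3d)
        assert sc.theta == pytest.approx(
            (3 * 0.15 / (math.pi * params3d.mu)) ** 0.25, rel=1e-12
        )
        assert sc.theta == pytest.approx(15.8, abs=0.05)

    def test_printed_3d_alpha(self, params3d):
        c, cm, mu = params3d.c_wt, params3d.c_m, params3d.mu
        expected = (
            3 * (cm - c) ** 3 / (math.pi * mu * (c**2 - 3 * c * cm + 3 * cm**2))
        ) ** 0.25
        assert scales(params3d).alpha == pytest.approx(expected, rel=1e-12)

    def test_beta_half_when_speed_doubles(self):
        for d in (1, 2, 3):
            p = MacroParams(0.2, 0.4, 1e-6, d)
            assert scales(p).beta == pytest.approx(0.5)

    def test_alpha_theta_beta_identity_random_draws(self, rng):
        # alpha^(d+1)/(alpha^(d+1)+theta^(d+1)) == beta^d to 1e-12
        for _ in range(100):
            d = rng.integers(1, 4)
            c_wt = rng.uniform(0.01, 1.0)
            c_m = c_wt * rng.uniform(1.01, 20.0)
            p = MacroParams(c_wt, c_m, 10 ** rng.uniform(-8, -3), int(d))
            sc = scales(p)
            lhs = sc.alpha ** (d + 1) / (sc.alpha ** (d + 1) + sc.theta ** (d + 1))
            assert lhs == pytest.approx(sc.beta**d, abs=1e-12, rel=1e-12)

    def test_equal_speeds_sentinel(self):
        sc = scales(MacroParams(0.3, 0.3, 1e-6, 3))
        assert sc.beta == 0.0 and math.isinf(sc.alpha) and not sc.sweep_possible


class TestArrivalAndRadiusDensities:
    def test_normalisation(self, params_any_d):
        kappa = scales(params_any_d).kappa
        val, _ = integrate.quad(
            lambda t: arrival_time_density(t, params_any_d), 0, 12 * kappa
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_cdf_matches_poisson_survival(self, params_any_d, rng):
        # 1 - P0(t) with lambda = mu int V_d (c s)^d ds equals the Weibull CDF
        d, c, mu = params_any_d.d, params_any_d.c_wt, params_any_d.mu
        kappa = scales(params_any_d).kappa
        for t in rng.uniform(0.1, 3.0, size=10) * kappa:
            lam = cumulative_intensity(
                lambda s: UNIT_BALL_VOLUME[d] * (c * s) ** d, mu, t
            ).lambda_value
            cdf, _ = integrate.quad(lambda u: arrival_time_density(u, params_any_d), 0, t)
            assert cdf == pytest.approx(1 - math.exp(-lam), rel=1e-6, abs=1e-9)

    def test_radius_density_change_of_variables(self, params_any_d, rng):
        c = params_any_d.c_wt
        x = rng.uniform(0.1, 3.0, size=8) * scales(params_any_d).theta
        np.testing.assert_allclose(
            radius_density(x, params_any_d),
            arrival_time_density(x / c, params_any_d) / c,
            rtol=1e-12,
        )

    def test_moments_printed_3d_values(self, params3d):
        mean, var = radius_moments(params3d)
        theta = scales(params3d).theta
        assert mean / theta == pytest.approx(0.91, abs=0.005)
        assert var / theta**2 == pytest.approx(0.065, abs=0.0005)

    def test_moments_1d_rayleigh(self):
        p = MacroParams(0.15, 0.31, 2.3e-6, 1)
        theta = scales(p).theta
        mean, var = radius_moments(p)
        assert mean == pytest.approx(theta * math.sqrt(math.pi) / 2, rel=1e-12)
        assert var == pytest.approx(theta**2 * (1 - math.pi / 4), rel=1e-12)

    def test_moments_match_weibull_sampling(self, params3d, rng):
        theta = scales(params3d).theta
        draws = theta * rng.weibull(4, size=1_000_000)
        mean, var = radius_moments(params3d)
        se_mean = draws.std() / 1000.0
        assert abs(draws.mean() - mean) < 3 * se_mean
        assert abs(draws.var() - var) < 3 * var * math.sqrt(2 / 1e6) * 2


class TestLocationDensities:
    def test_conditional_forms(self):
        y = np.array([0.5, 1.0, 1.9])
        np.testing.assert_allclose(
            location_density_conditional(y, 2.0, 3), 3 * y**2 / 8.0
        )
        np.testing.assert_allclose(location_density_conditional(y, 2.0, 1), 0.5)

    def test_conditional_normalises_exactly(self, params_any_d):
        d = params_any_d.d
        x = 7.3
        val, _ = integrate.quad(lambda y: location_density_conditional(y, x, d), 0, x)
        assert val == pytest.approx(1.0, rel=1e-10)

    def test_marginal_matches_direct_marginalisation(self, params_any_d, rng):
        # oracle: integrate f_Y(y|x) f_X(x) dx by adaptive quadrature
        theta = scales(params_any_d).theta
        for y in rng.uniform(0.05, 2.0, size=10) * theta:
            direct, _ = integrate.quad(
                lambda x: location_density_conditional(y, x, params_any_d.d)
                * radius_density(x, params_any_d),
                y,
                12 * theta,
                limit=200,
            )
            assert location_density(y, params_any_d) == pytest.approx(direct, rel=1e-6)

    def test_printed_3d_moments(self, params3d):
        mean, var = location_moments(params3d, "quadrature")
        theta = scales(params3d).theta
        assert mean / theta == pytest.approx(0.68, abs=0.005)
        assert var / theta**2 == pytest.approx(0.070, abs=0.0008)

    def test_quadrature_agrees_with_closed_form(self, params_any_d):
        mq, vq = location_moments(params_any_d, "quadrature")
        mc, vc = location_moments(params_any_d, "closed_form")
        assert mq == pytest.approx(mc, rel=1e-5)
        assert vq == pytest.approx(vc, rel=1e-4)


class TestConditionalSweepProbability:
    def test_vanishing_radius_limit(self, params_any_d):
        assert conditional_sweep_prob(1e-9, 0.0, params_any_d, "exact") == pytest.approx(1.0)
        assert conditional_sweep_prob(0.0, 0.0, params_any_d, "approx") == 1.0

    def test_approx_is_printed_3d_form(self, params3d, rng):
        alpha = scales(params3d).alpha
        x = rng.uniform(0.1, 3.0, size=6) * scales(params3d).theta
        np.testing.assert_allclose(
            conditional_sweep_prob(x, np.zeros_like(x), params3d, "approx"),
            np.exp(-((x / alpha) ** 4)),
            rtol=1e-12,
        )

    def test_y0_bound_dominates_exact(self, params_any_d, rng):
        # the y = 0 approximation is an upper bound for every y > 0
        theta = scales(params_any_d).theta
        x = rng.uniform(0.05, 3.0, size=200) * theta
        y = rng.uniform(0.0, 1.0, size=200) * x
        exact = conditional_sweep_prob(x, y, params_any_d, "exact")
        approx = conditional_sweep_prob(x, np.zeros_like(x), params_any_d, "approx")
        assert np.all(exact <= approx * (1 + 1e-12))

    def test_unknown_method_rejected(self, params3d):
        with pytest.raises(ValueError):
            conditional_sweep_prob(1.0, 0.0, params3d, "magic")


class TestSweepProbability:
    @pytest.mark.parametrize(
        "d,ratio,expected", [(3, 2.0, 0.125), (2, 2.0, 0.25), (3, 1.1, (1 - 1 / 1.1) ** 3)]
    )
    def test_closed_form_worked_examples(self, d, ratio, expected):
        p = MacroParams(0.15, 0.15 * ratio, 2.3e-6, d)
        assert sweep_probability(p, "closed_form") == pytest.approx(expected, rel=1e-9)

    def test_zero_when_speeds_equal(self):
        assert sweep_probability(MacroParams(0.2, 0.2, 1e-6, 3)) == 0.0

    def test_numeric_below_closed_form(self, params_any_d):
        num = sweep_probability(params_any_d, "numeric")
        assert 0 < num <= sweep_probability(params_any_d, "closed_form")

    def test_numeric_independent_of_mutation_rate(self, params3d):
        base = sweep_probability(params3d, "numeric")
        for factor in (0.1, 100.0):
            p = MacroParams(params3d.c_wt, params3d.c_m, params3d.mu * factor, 3)
            assert sweep_probability(p, "numeric") == pytest.approx(base, rel=1e-3)

    def test_monotone_in_speeds(self):
        up = [sweep_probability(MacroParams(0.15, cm, 1e-6, 2)) for cm in (0.2, 0.3, 0.5)]
        assert up == sorted(up)
        down = [sweep_probability(MacroParams(cw, 0.5, 1e-6, 2)) for cw in (0.1, 0.2, 0.3)]
        assert down == sorted(down, reverse=True)

    def test_dimension_ordering(self):
        probs = [sweep_probability(MacroParams(0.15, 0.31, 1e-6, d)) for d in (1, 2, 3)]
        assert probs[0] >= probs[1] >= probs[2]

    def test_refined_1d_between_numeric_and_bound(self):
        p = MacroParams(0.15, 0.31, 2.3e-6, 1)
        refined = sweep_probability(p, "refined_1d")
        assert sweep_probability(p, "numeric") <= refined <= scales(p).beta
        assert REFINED_1D_Y2_COEFF == 0.28125

    def test_dsweep_integral_identity(self, rng):
        # int exp(-(x/alpha)^(d+1)) f_X dx == beta^d: the derivation of the
        # d-dimensional closed form, checked by quadrature
        for d in (1, 2, 3):
            c_wt = rng.uniform(0.05, 0.5)
            p = MacroParams(c_wt, c_wt * rng.uniform(1.2, 5.0), 1e-6, d)
            sc = scales(p)
            val, _ = integrate.quad(
                lambda x: math.exp(-((x / sc.alpha) ** (d + 1)))
                * radius_density(x, p),
                0,
                12 * sc.theta,
            )
            assert val == pytest.approx(sc.beta**d, rel=1e-7)


class TestRateForm:
    def test_worked_example(self):
        # a_wt = 0.09, a_m = 0.36 -> (1 - 1/2)^2
        assert sweep_probability_from_rates(0.91, 1.0, 1.36, 2) == pytest.approx(0.25)

    def test_clipped_when_advantages_equal(self):
        assert sweep_probability_from_rates(1.0, 1.5, 2.0, 2) == 0.0
        assert sweep_probability_from_rates(1.0, 1.75, 2.0, 2) == 0.0

    def test_matches_speed_form_for_any_diffusivity(self, rng):
        r_re, r_wt, r_m, d = 0.91, 1.0, 1.4, 3
        for D in rng.uniform(0.01, 5.0, size=5):
            c_wt = 2 * math.sqrt(D * (r_wt - r_re))
            c_m = 2 * math.sqrt(D * (r_m - r_wt))
            p = MacroParams(c_wt, c_m, 1e-6, d)
            assert sweep_probability(p) == pytest.approx(
                sweep_probability_from_rates(r_re, r_wt, r_m, d), rel=1e-12
            )

    def test_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            sweep_probability_from_rates(1.0, 0.9, 1.3, 2)


class TestPosteriorRadius:
    def test_approx_normalises_and_mean(self, params3d):
        sc = scales(params3d)
        val, _ = integrate.quad(
            lambda x: posterior_radius_given_sweep(x, params3d, "approx"),
            0,
            12 * sc.theta,
        )
        assert val == pytest.approx(1.0, abs=1e-8)
        mean, _ = integrate.quad(
            lambda x: x * posterior_radius_given_sweep(x, params3d, "approx"),
            0,
            12 * sc.theta,
        )
        assert mean == pytest.approx(special.gamma(1.25) * sc.beta**0.75 * sc.theta, rel=1e-6)

    def test_numeric_bayes_consistency(self, params3d):
        # posterior == Pr(sweep|X=x) f_X(x) / Pr(sweep), all three factors
        # computed independently
        from rangesweep.analytic import _conditional_given_x

        sc = scales(params3d)
        xs = np.linspace(0.2, 2.0, 10) * sc.theta
        post = posterior_radius_given_sweep(xs, params3d, "numeric")
        norm = sweep_probability(params3d, "numeric")
        expect = _conditional_given_x(xs, params3d, sc.theta) * radius_density(xs, params3d) / norm
        np.testing.assert_allclose(post, expect, rtol=1e-10)

    def test_equal_speeds_rejected(self):
        with pytest.raises(ValueError):
            posterior_radius_given_sweep(1.0, MacroParams(0.3, 0.3, 1e-6, 3))


class TestCancerUnits:
    def test_worked_volume_time_example(self):
        um_day, _ = cancer_speed_estimate(1.0, 20.0)
        assert um_day == pytest.approx((3 / (4 * math.pi)) ** (1 / 3) * 1e4 / (20 * 365.25), rel=1e-9)
        assert um_day == pytest.approx(0.85, abs=0.01)

    def test_linear_in_generation_time(self):
        _, c1 = cancer_speed_estimate(2.0, 10.0, generation_days=4)
        _, c2 = cancer_speed_estimate(2.0, 10.0, generation_days=8)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_unit_cancellation(self):
        um_day, c = cancer_speed_estimate(5.0, 7.0, cell_diameter_um=3.0, generation_days=3.0)
        assert c == pytest.approx(um_day, rel=1e-12)
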