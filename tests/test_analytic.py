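import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coastdiff import (DuhamelIntegralSpec, ModelParams, duhamel_F,
                       model1_density, model1_moments, model1_occupancy_pdf,
                       model1_total, model2_cbd_density, model2_cbd_total,
                       model2_sync_density, model2_sync_total)
from coastdiff.analytic import (SPREAD_RATE_COEFFICIENT,
                                model1_occupancy_pdf_integral_form)

# frozen from an independent quadrature of (2/sqrt(pi)) * int_y^inf e^{-z^2} dz
ERFC_HALF = 0.4795001221869536


class TestModel1Density:
    def test_boundary_value(self, params):
        assert model1_density(0.0, 1.0, params) == pytest.approx(1.0)

    def test_against_quadrature_oracle(self, params):
        # x=10, t=100, D=1 -> erfc(0.5)
        assert model1_density(10.0, 100.0, params) == pytest.approx(
            ERFC_HALF, abs=1e-10)

    def test_far_field(self, params):
        assert model1_density(1e6, 1.0, params) == pytest.approx(0.0, abs=1e-10)

    def test_initial_condition(self, params):
        assert model1_density(5.0, 0.0, params) == 0.0
        assert model1_density(0.0, 0.0, params) == 0.0

    def test_negative_arguments(self, params):
        with pytest.raises(ValueError):
            model1_density(-1.0, 1.0, params)
        with pytest.raises(ValueError):
            model1_density(1.0, -1.0, params)

    def test_vectorized(self, params):
        x = np.array([0.0, 10.0, 1e6])
        out = model1_density(x, 100.0, params)
        assert out.shape == (3,)
        assert out[0] == pytest.approx(1.0)


class TestModel1Total:
    def test_t_zero(self, params):
        assert model1_total(0.0, params) == 0.0

    def test_matches_trapezoid_integral(self, diffusion_only):
        x = np.arange(0.0, 100.0001, 0.1)
        approx = np.trapezoid(model1_density(x, 100.0, diffusion_only), dx=0.1)
        assert model1_total(100.0, diffusion_only) == pytest.approx(
            approx, rel=1e-3)
        assert model1_total(100.0, diffusion_only) == pytest.approx(
            2.0 * math.sqrt(100.0 / math.pi))

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.01, 500.0))
    def test_sqrt_scaling(self, t):
        p = ModelParams(D=1.0, N0=1.0)
        assert model1_total(4 * t, p) == pytest.approx(2 * model1_total(t, p),
                                                       rel=1e-12)


class TestModel1OccupancyPdf:
    def test_normalization(self, params):
        from scipy.integrate import quad
        val, _ = quad(lambda x: model1_occupancy_pdf(x, 100.0, params),
                      0.0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_monotone_nonincreasing(self, params):
        x = np.linspace(0.0, 200.0, 4001)
        p = model1_occupancy_pdf(x, 100.0, params)
        assert np.all(np.diff(p) <= 1e-15)

    @pytest.mark.parametrize("x", [0.0, 5.0, 10.0, 50.0])
    def test_two_printed_forms_agree(self, x, params):
        a = model1_occupancy_pdf(x, 100.0, params)
        b = model1_occupancy_pdf_integral_form(x, 100.0, params)
        assert a == pytest.approx(b, abs=1e-10)

    def test_undefined_at_t_zero(self, params):
        with pytest.raises(ValueError):
            model1_occupancy_pdf(1.0, 0.0, params)


class TestModel1Moments:
    def test_variance_coefficient_to_12_digits(self, params):
        m = model1_moments(100.0, params)
        assert m.variance / 100.0 == pytest.approx(SPREAD_RATE_COEFFICIENT,
                                                   abs=1e-12)
        assert round(m.variance / 100.0, 2) == 0.55

    def test_mean_matches_quadrature(self, params):
        # oracle: quad of x * p(x, t) computed independently -> 8.86226925452758
        m = model1_moments(100.0, params)
        assert m.mean_x == pytest.approx(8.86226925452758, abs=1e-9)

    def test_variance_identity(self, params):
        m = model1_moments(37.0, params)
        assert m.variance == pytest.approx(m.second_moment - m.mean_x**2,
                                           abs=1e-12)

    def test_t_nonpositive(self, params):
        with pytest.raises(ValueError):
            model1_moments(0.0, params)


class TestModel2Sync:
    def test_boundary_growth(self, params):
        # t=100, r=0.01 -> boundary value e
        assert model2_sync_density(0.0, 100.0, params) == pytest.approx(math.e)

    def test_equals_scaled_model1(self, params):
        x = np.linspace(0.0, 50.0, 101)
        lhs = model2_sync_density(x, 20.0, params)
        rhs = math.exp(0.01 * 20.0) * model1_density(x, 20.0, params)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-15)

    def test_initial_condition(self, params):
        assert model2_sync_density(5.0, 0.0, params) == 0.0

    def test_total(self, params):
        assert model2_sync_total(0.0, params) == 0.0
        expect = math.e * 2.0 * math.sqrt(100.0 / math.pi)
        assert model2_sync_total(100.0, params) == pytest.approx(expect)
        # trapezoid integral route
        x = np.arange(0.0, 150.0001, 0.05)
        approx = np.trapezoid(model2_sync_density(x, 100.0, params), dx=0.05)
        assert model2_sync_total(100.0, params) == pytest.approx(approx, rel=1e-3)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.01, 300.0))
    def test_ratio_is_exponential(self, t):
        p = ModelParams(D=1.0, r=0.01, N0=1.0)
        ratio = model2_sync_total(t, p) / model1_total(t, p)
        assert ratio == pytest.approx(math.exp(0.01 * t), rel=1e-12)

    def test_requires_growth(self, diffusion_only):
        with pytest.raises(ValueError):
            model2_sync_density(1.0, 1.0, diffusion_only)


class TestDuhamelF:
    def test_empty_integral(self):
        assert duhamel_F(DuhamelIntegralSpec(a=0.0, b=1.0)) == 0.0

    def test_divergent_at_b_zero(self):
        with pytest.raises(ValueError):
            duhamel_F(DuhamelIntegralSpec(a=1.0, b=0.0))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            DuhamelIntegralSpec(a=-1.0, b=1.0)
        with pytest.raises(ValueError):
            DuhamelIntegralSpec(a=1.0, b=1.0, tolerance=1e-3)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.05, 3.0), st.floats(0.05, 3.0), st.floats(0.05, 2.0))
    def test_strictly_increasing_in_a(self, a, da, b):
        f1 = duhamel_F(DuhamelIntegralSpec(a=a, b=b))
        f2 = duhamel_F(DuhamelIntegralSpec(a=a + da, b=b))
        assert f2 > f1

    def test_small_b_limit(self):
        # b*F(a, b) -> 2*sqrt(pi) as b -> 0+ (regularized Gamma(1/2) limit)
        b = 1e-6
        val = b * duhamel_F(DuhamelIntegralSpec(a=1.0, b=b))
        assert val / (2.0 * math.sqrt(math.pi)) == pytest.approx(1.0, abs=1e-4)

    def test_against_brute_force_quadrature(self):
        # moderate (a, b) where naive quadrature is still trustworthy
        from scipy.integrate import quad
        a, b = 1.0, 2.0
        ref, _ = quad(lambda w: w**-1.5 * np.exp(w - b * b / (4 * w)),
                      0.0, a, limit=200)
        assert duhamel_F(DuhamelIntegralSpec(a=a, b=b)) == pytest.approx(
            ref, rel=1e-8)


class TestModel2Cbd:
    def test_boundary_limit(self, params):
        assert model2_cbd_density(0.0, 1.0, params) == pytest.approx(1.0)
        # continuity: x -> 0+ approaches the imposed boundary value
        assert model2_cbd_density(1e-6, 1.0, params) == pytest.approx(
            1.0, abs=1e-4)

    def test_zero_growth_limit_recovers_diffusion(self):
        slow = ModelParams(D=1.0, r=1e-8, N0=1.0)
        ref = model1_density(5.0, 50.0, ModelParams(D=1.0, N0=1.0))
        assert model2_cbd_density(5.0, 50.0, slow) == pytest.approx(
            ref, abs=1e-4)

    def test_growth_unbounded_in_time(self, params):
        v = [model2_cbd_density(5.0, t, params) for t in (10.0, 100.0, 300.0, 600.0)]
        assert all(b > a for a, b in zip(v, v[1:]))
        assert v[-1] > 10.0 * v[0]

    def test_initial_condition(self, params):
        assert model2_cbd_density(5.0, 0.0, params) == 0.0

    def test_requires_growth(self, diffusion_only):
        with pytest.raises(ValueError):
            model2_cbd_density(1.0, 1.0, diffusion_only)


class TestModel2CbdTotal:
    def test_t_zero(self, params):
        assert model2_cbd_total(0.0, params) == 0.0

    def test_two_routes_agree(self, params):
        a = model2_cbd_total(100.0, params, method="erfi")
        b = model2_cbd_total(100.0, params, method="quadrature")
        assert a == pytest.approx(b, rel=1e-8)

    def test_small_rt_recovers_pure_diffusion_total(self):
        p = ModelParams(D=1.0, r=0.01, N0=1.0)
        t = 0.01  # r*t = 1e-4
        assert model2_cbd_total(t, p) == pytest.approx(
            model1_total(t, p), rel=1e-4)

    def test_unknown_method(self, params):
        with pytest.raises(ValueError):
            model2_cbd_total(1.0, params, method="nope")


class TestTildeTransform:
    def test_consistency(self, params):
        # exp(-r t) * synchronized solution satisfies the pure-diffusion form
        x = np.linspace(0.0, 60.0, 301)
        t = 42.0
        tilde = math.exp(-params.r * t) * model2_sync_density(x, t, params)
        np.testing.assert_allclose(tilde, model1_density(x, t, params),
                                   rtol=1e-14, atol=1e-300)
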