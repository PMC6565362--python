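"""Circular-statistics primitives: densities, resultants, vector algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from multicue.circstats import (
    KAPPA_CAP,
    VonMises,
    circ_estimate,
    inv_resultant,
    resultant_length,
    vm_pdf,
    vm_product,
    vm_ratio,
    wrap_deg,
)

angles = st.floats(-1e4, 1e4, allow_nan=False)
kappas = st.floats(0.0, 1e3, allow_nan=False)


def quad_resultant(kappa: float) -> float:
    """Independent quadrature oracle for the mean resultant length."""
    num = quad(lambda t: math.cos(t) * math.exp(kappa * (math.cos(t) - 1.0)),
               -math.pi, math.pi)[0]
    den = quad(lambda t: math.exp(kappa * (math.cos(t) - 1.0)),
               -math.pi, math.pi)[0]
    return num / den


@given(angles)
@settings(max_examples=200, deadline=None)
def test_wrap_deg_range_and_idempotence(x):
    w = wrap_deg(x)
    assert -180.0 < w <= 180.0
    assert wrap_deg(w) == pytest.approx(w, abs=1e-9)
    # wrapping preserves the angle modulo 360
    assert math.isclose(math.cos(math.radians(x)), math.cos(math.radians(w)),
                        abs_tol=1e-9)


class TestVonMises:
    def test_mu_wrapped_and_kappa_validated(self):
        d = VonMises(370.0, 2.0)
        assert d.mu == pytest.approx(10.0)
        with pytest.raises(ValueError):
            VonMises(0.0, -1.0)
        with pytest.raises(ValueError):
            VonMises(0.0, float("inf"))

    def test_kappa_zero_flags_undefined_mu(self):
        d = VonMises(45.0, 0.0)
        assert not d.mu_defined
        assert VonMises.uniform().kappa == 0.0

    @given(st.floats(-180.0, 180.0), st.floats(1e-3, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_vector_round_trip(self, mu, kappa):
        d = VonMises(mu, kappa)
        back = d.to_vector().to_vonmises()
        assert abs(wrap_deg(back.mu - d.mu)) < 1e-10 * max(1.0, abs(mu))
        assert back.kappa == pytest.approx(kappa, rel=1e-10)

    def test_vector_length_equals_kappa(self):
        v = VonMises(30.0, 7.0).to_vector()
        assert v.length == pytest.approx(7.0, rel=1e-12)


class TestPdf:
    @pytest.mark.parametrize("kappa", [0.5, 3.0, 50.0, 1000.0])
    def test_normalization_mode_and_symmetry(self, kappa):
        d = VonMises(37.0, kappa)
        total = quad(lambda t: vm_pdf(math.degrees(t), d), -math.pi, math.pi,
                     limit=200)[0]
        assert total == pytest.approx(1.0, abs=1e-8)
        grid = np.linspace(-180.0, 180.0, 721)
        dens = vm_pdf(grid, d)
        if kappa <= 100.0:  # far tails underflow double precision beyond
            assert np.all(dens > 0)
        assert grid[np.argmax(dens)] == pytest.approx(37.0, abs=0.5)
        assert vm_pdf(37.0 + 25.0, d) == pytest.approx(vm_pdf(37.0 - 25.0, d),
                                                       rel=1e-12)

    def test_uniform_limit(self):
        d = VonMises(0.0, 0.0)
        assert vm_pdf(123.0, d) == pytest.approx(1.0 / (2 * math.pi))


class TestResultant:
    def test_against_quadrature_oracle(self):
        # frozen from the quadrature oracle, and recomputed live
        assert resultant_length(2.0) == pytest.approx(0.6977746579640082,
                                                      abs=1e-12)
        for kappa in (0.3, 2.0, 8.0):
            assert resultant_length(kappa) == pytest.approx(
                quad_resultant(kappa), abs=1e-10)

    def test_limits_and_monotonicity(self):
        assert resultant_length(0.0) == 0.0
        assert resultant_length(1e6) > 0.999999
        ks = np.geomspace(1e-3, 1e3, 50)
        rs = resultant_length(ks)
        assert np.all(np.diff(rs) > 0)
        with pytest.raises(ValueError):
            resultant_length(-0.1)

    @pytest.mark.parametrize("kappa", [0.5, 5.0, 50.0])
    def test_inverse_round_trip(self, kappa):
        assert inv_resultant(resultant_length(kappa)) == pytest.approx(
            kappa, rel=1e-6)

    def test_inverse_at_oracle_value(self):
        assert inv_resultant(quad_resultant(10.0)) == pytest.approx(10.0,
                                                                    rel=1e-6)

    def test_inverse_domain(self):
        assert inv_resultant(0.0) == 0.0
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                inv_resultant(bad)

    @pytest.mark.parametrize("kappa", [100.0, 1000.0])
    def test_large_kappa_gaussian_limit(self, kappa):
        # for sharp distributions the angular variance approaches 1/kappa
        d = VonMises(0.0, kappa)
        var = quad(lambda t: t * t * vm_pdf(math.degrees(t), d),
                   -math.pi, math.pi, limit=200)[0]
        assert var == pytest.approx(1.0 / kappa, rel=0.02)


class TestVectorAlgebra:
    @pytest.mark.parametrize("theta", [10.0, 45.0, 80.0])
    def test_opposite_equal_cues_integrate_to_zero(self, theta):
        out = vm_product(VonMises(theta, 5.0), VonMises(-theta, 5.0))
        assert out.mu == pytest.approx(0.0, abs=1e-10)

    def test_opposite_equal_cues_beyond_quadrature(self):
        # beyond +-90 deg the resultant flips to the antipode; at exactly
        # +-90 deg it cancels and the integrated distribution is flat
        out = vm_product(VonMises(170.0, 5.0), VonMises(-170.0, 5.0))
        assert out.mu == pytest.approx(180.0)
        out = vm_product(VonMises(90.0, 5.0), VonMises(-90.0, 5.0))
        assert out.kappa == 0.0 and not out.mu_defined

    def test_collinear_and_right_angle(self):
        out = vm_product(VonMises(0.0, 3.0), VonMises(0.0, 4.5))
        assert (out.mu, out.kappa) == (pytest.approx(0.0),
                                       pytest.approx(7.5))
        out = vm_product(VonMises(0.0, 2.0), VonMises(90.0, 2.0))
        assert out.mu == pytest.approx(45.0)
        assert out.kappa == pytest.approx(2.0 * math.sqrt(2.0))

    def test_product_matches_pointwise_density_product(self):
        d1, d2 = VonMises(-20.0, 3.0), VonMises(40.0, 1.5)
        out = vm_product(d1, d2)
        grid = np.linspace(-179.0, 180.0, 360)
        # the pointwise product must be proportional to the returned density
        ratio = vm_pdf(grid, d1) * vm_pdf(grid, d2) / vm_pdf(grid, out)
        assert np.std(ratio) / np.mean(ratio) < 1e-10

    def test_cancellation_returns_flagged_uniform(self):
        out = vm_product(VonMises(0.0, 2.0), VonMises(180.0, 2.0))
        assert out.kappa == 0.0 and not out.mu_defined

    @given(st.floats(-180, 180), st.floats(0, 50), st.floats(-180, 180),
           st.floats(0, 50), st.floats(-180, 180), st.floats(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_commutative_associative(self, m1, k1, m2, k2, m3, k3):
        d1, d2, d3 = VonMises(m1, k1), VonMises(m2, k2), VonMises(m3, k3)
        ab = vm_product(d1, d2).to_vector() + d3.to_vector()
        bc = d1.to_vector() + vm_product(d2, d3).to_vector()
        assert math.hypot(ab.x - bc.x, ab.y - bc.y) < 1e-10 * (1 + k1 + k2 + k3)
        ba = vm_product(d2, d1)
        ab2 = vm_product(d1, d2)
        assert abs(ab2.kappa - ba.kappa) < 1e-10 * (1 + k1 + k2)

    def test_ratio_is_shifted_product(self):
        d1 = VonMises(0.0, 50.0)
        d2 = VonMises(20.0, 25.0)
        r = vm_ratio(d1, d2)
        s = vm_product(d1, VonMises(200.0, 25.0))
        assert (r.mu, r.kappa) == (s.mu, s.kappa)

    def test_ratio_examples(self):
        out = vm_ratio(VonMises(0.0, 3.0), VonMises(180.0, 4.0))
        assert out.mu == pytest.approx(0.0) and out.kappa == pytest.approx(7.0)
        same = vm_ratio(VonMises(12.0, 5.0), VonMises(12.0, 5.0))
        assert same.kappa == 0.0 and not same.mu_defined


class TestCircEstimate:
    def test_degenerate_samples_saturate(self):
        d = circ_estimate([37.0] * 50)
        assert d.mu == pytest.approx(37.0)
        assert d.kappa == KAPPA_CAP

    def test_uniform_grid_has_zero_concentration(self):
        d = circ_estimate(np.linspace(-179.0, 180.0, 360))
        assert d.kappa < 1e-6

    def test_parameter_recovery_against_independent_sampler(self, rng):
        # oracle: numpy's own von Mises sampler, independent of this module
        samples = np.degrees(rng.vonmises(0.0, 10.0, size=50_000))
        d = circ_estimate(samples)
        assert d.mu == pytest.approx(0.0, abs=0.5)
        assert d.kappa == pytest.approx(10.0, rel=0.05)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            circ_estimate([1.0])
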