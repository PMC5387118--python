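"""Unit and property tests for the single-impact survival chain."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from cellspray.impact import (
    CellProperties,
    FluidProperties,
    ModelConstants,
    SubstrateProperties,
    SurvivalParameters,
    bare_spreading_ratio,
    clamp_spreading,
    cushioned_deformation,
    deformation,
    effective_impact,
    oblate_area,
    predict_eta,
    predict_single,
    reynolds_number,
    spheroid_height,
    spreading_from_deformation,
    substrate_stiffness,
    survival_probability,
    weber_number,
)

CELL = CellProperties()
FLUID = FluidProperties()
HARD = SubstrateProperties.hard()
POOL = SubstrateProperties.liquid_pool()


def oblate_area_by_quadrature(d_eq: float, h: float) -> float:
    """Independent oracle: surface-of-revolution quadrature for the area of
    an oblate spheroid with equatorial diameter d_eq and polar diameter h."""
    a, c = d_eq / 2.0, h / 2.0

    def arc(theta):
        return (a * math.cos(theta)
                * math.sqrt(a**2 * math.sin(theta)**2 + c**2 * math.cos(theta)**2))

    val, _ = quad(arc, -math.pi / 2, math.pi / 2, epsabs=0, epsrel=1e-12)
    return 2.0 * math.pi * val


# --------------------------------------------------------------------------
# dimensionless groups
# --------------------------------------------------------------------------


class TestDimensionlessNumbers:
    def test_weber_direct_value(self):
        # rho V^2 D / sigma evaluated by hand
        assert weber_number(1015, 10, 15e-6, 0.072) == pytest.approx(21.145833, rel=1e-6)

    def test_weber_zero_velocity_and_quadratic_scaling(self):
        assert weber_number(1015, 0, 15e-6, 0.072) == 0.0
        assert weber_number(1015, 20, 15e-6, 0.072) == pytest.approx(
            4 * weber_number(1015, 10, 15e-6, 0.072))

    def test_reynolds_direct_value_and_viscosity_scaling(self):
        assert reynolds_number(1015, 10, 15e-6, 0.012) == pytest.approx(12.6875, rel=1e-6)
        assert reynolds_number(1015, 0, 15e-6, 0.012) == 0.0
        assert reynolds_number(1015, 10, 15e-6, 0.024) == pytest.approx(
            0.5 * reynolds_number(1015, 10, 15e-6, 0.012))

    @pytest.mark.parametrize("bad", [(0, 1, 1e-5, 0.07), (1000, 1, -1e-5, 0.07),
                                     (1000, 1, 1e-5, 0), (1000, -1, 1e-5, 0.07)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            weber_number(*bad)


# --------------------------------------------------------------------------
# substrate mapping
# --------------------------------------------------------------------------


class TestSubstrate:
    def test_stiffness_law(self):
        assert substrate_stiffness(0.0) == 0.0
        assert substrate_stiffness(0.1) == pytest.approx(0.5)
        assert substrate_stiffness(0.2) == 1.0  # saturation at the hard-surface value
        assert substrate_stiffness(0.5) == 1.0

    def test_stiffness_domain(self):
        with pytest.raises(ValueError):
            substrate_stiffness(-0.1)
        with pytest.raises(ValueError):
            substrate_stiffness(1.5)

    def test_effective_impact_endpoints_exact(self):
        d0, v0 = 30e-6, 12.0
        assert effective_impact(d0, v0, 1.0) == (d0, v0)
        assert effective_impact(d0, v0, 0.0) == (2 * d0, 0.5 * v0)

    @given(st.floats(0.001, 0.999))
    def test_effective_impact_interpolates_monotonically(self, s):
        d0, v0 = 30e-6, 12.0
        de, ve = effective_impact(d0, v0, s)
        assert d0 < de < 2 * d0
        assert 0.5 * v0 < ve < v0
        de2, ve2 = effective_impact(d0, v0, min(s + 0.001, 1.0))
        assert de2 <= de and ve2 >= ve

    def test_effective_impact_rejects_bad_stiffness(self):
        with pytest.raises(ValueError):
            effective_impact(30e-6, 12.0, 1.2)


# --------------------------------------------------------------------------
# spreading law
# --------------------------------------------------------------------------


class TestSpreading:
    def test_low_weber_plateau(self):
        c = ModelConstants()
        plateau = bare_spreading_ratio(0.0, 10.0, c)
        assert plateau >= 1.0
        for we in (0.5, 2.0, 4.9):
            assert bare_spreading_ratio(we, 10.0, c) == plateau

    def test_monotone_above_threshold_and_continuous_at_it(self):
        c = ModelConstants()
        assert bare_spreading_ratio(50, 1e3, c) > bare_spreading_ratio(10, 1e3, c)
        below = bare_spreading_ratio(c.weber_low - 1e-9, 1e3, c)
        above = bare_spreading_ratio(c.weber_low + 1e-9, 1e3, c)
        assert above == pytest.approx(below, rel=1e-6)

    def test_out_of_validity_counts_but_does_not_fail(self):
        from cellspray.impact import reset_validity_counts, validity_counts
        reset_validity_counts()
        bare_spreading_ratio(1e4, 2.0)  # wildly outside the capillary regime
        assert validity_counts().get("spreading_regime", 0) == 1


# --------------------------------------------------------------------------
# geometry: spheroid height, deformation, area
# --------------------------------------------------------------------------


class TestGeometry:
    def test_spheroid_height_volume_conservation(self):
        assert spheroid_height(10e-6, 10e-6) == pytest.approx(10e-6)
        assert spheroid_height(10e-6, 20e-6) == pytest.approx(2.5e-6)
        d, dm = 13e-6, 31e-6
        h = spheroid_height(d, dm)
        assert (math.pi / 6) * dm**2 * h == pytest.approx((math.pi / 6) * d**3, rel=1e-14)

    def test_deformation_endpoints_and_monotonicity(self):
        d = 10e-6
        assert deformation(d, d) == 0.0
        assert deformation(d, 1e6 * d) == pytest.approx(1.0, abs=1e-9)
        m15, m2 = deformation(d, 1.5 * d), deformation(d, 2 * d)
        assert 0 < m15 < m2 < 1

    def test_deformation_rejects_compression(self):
        with pytest.raises(ValueError):
            deformation(10e-6, 9e-6)

    @pytest.mark.parametrize("m", [0.1, 0.5, 0.9])
    def test_spreading_deformation_round_trip(self, m):
        d = 13e-6
        assert deformation(d, spreading_from_deformation(m, d)) == pytest.approx(
            m, rel=1e-12)

    def test_spreading_from_deformation_limits(self):
        assert spreading_from_deformation(0.0, 13e-6) == pytest.approx(13e-6)
        assert spreading_from_deformation(0.9, 13e-6) > spreading_from_deformation(0.5, 13e-6)
        with pytest.raises(ValueError):
            spreading_from_deformation(1.0, 13e-6)

    def test_oblate_area_sphere_limit(self):
        assert oblate_area(10e-6, 10e-6) == pytest.approx(math.pi * (10e-6) ** 2, rel=1e-12)

    def test_oblate_area_matches_quadrature_oracle(self, rng):
        for _ in range(100):
            d_eq = rng.uniform(5e-6, 50e-6)
            h = d_eq * rng.uniform(0.02, 1.0)
            assert oblate_area(d_eq, h) == pytest.approx(
                oblate_area_by_quadrature(d_eq, h), rel=1e-9)

    def test_flattening_increases_area_at_fixed_volume(self):
        d = 10e-6
        dm = 20e-6
        assert oblate_area(dm, spheroid_height(d, dm)) > math.pi * d**2

    def test_oblate_area_rejects_prolate(self):
        with pytest.raises(ValueError):
            oblate_area(10e-6, 11e-6)

    def test_clamp_takes_the_smallest(self):
        assert clamp_spreading(12e-6, 15e-6, 20e-6) == 12e-6
        assert clamp_spreading(25e-6, 15e-6, 20e-6) == 15e-6
        assert clamp_spreading(18e-6, 30e-6, 16e-6) == 16e-6

    def test_literal_clamp_ignores_cushioned_value(self):
        c = ModelConstants(literal_clamp=True)
        assert clamp_spreading(12e-6, 15e-6, 20e-6, c) == 15e-6


# --------------------------------------------------------------------------
# cushioning
# --------------------------------------------------------------------------


class TestCushioning:
    def test_bare_cell_limit(self):
        for mu_ratio in (0.01, 0.5, 1.0, 10.0):
            assert cushioned_deformation(0.8, 1.0, mu_ratio) == pytest.approx(0.8)

    def test_larger_droplets_cushion_more(self):
        m0 = 0.8
        m_big = cushioned_deformation(m0, 3.0, 0.1)
        m_small = cushioned_deformation(m0, 1.5, 0.1)
        assert m_big < m_small < m0

    def test_viscous_droplets_cushion_less(self):
        m0 = 0.8
        assert cushioned_deformation(m0, 3.0, 1.0) > cushioned_deformation(m0, 3.0, 0.1)

    def test_domain(self):
        with pytest.raises(ValueError):
            cushioned_deformation(0.5, 0.9, 0.1)
        with pytest.raises(ValueError):
            cushioned_deformation(1.5, 2.0, 0.1)

    @given(st.floats(0.0, 0.999), st.floats(1.0, 10.0), st.floats(0.01, 10.0))
    def test_cushioned_deformation_bounded(self, m0, d_ratio, mu_ratio):
        m = cushioned_deformation(m0, d_ratio, mu_ratio)
        assert 0.0 <= m <= m0 + 1e-15


# --------------------------------------------------------------------------
# survival law
# --------------------------------------------------------------------------


class TestSurvival:
    def test_anchors(self):
        p = SurvivalParameters()
        assert survival_probability(1.5, p) == pytest.approx(0.5)
        assert survival_probability(1.0, p) == pytest.approx(1.0)
        assert survival_probability(2.0, p) == pytest.approx(0.0)
        assert survival_probability(0.5, p) == 1.0  # compression is harmless

    def test_monotone_decreasing(self):
        p = SurvivalParameters()
        assert survival_probability(1.2, p) > survival_probability(1.8, p)
        g = np.linspace(0, 3, 301)
        eta = survival_probability(g, p)
        assert np.all(np.diff(eta) <= 1e-15)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(-0.1)


# --------------------------------------------------------------------------
# full chain
# --------------------------------------------------------------------------


class TestPredictSingle:
    def test_no_impact_no_damage(self):
        out = predict_single(CELL, 39e-6, 0.0, FLUID, HARD)
        assert out.eta == pytest.approx(1.0, abs=0.02)
        assert out.gamma == pytest.approx(1.0, abs=0.02)

    def test_velocity_monotonicity_reference_case(self):
        etas = [predict_single(CELL, 3 * CELL.diameter, v, FLUID, HARD).eta
                for v in np.linspace(0, 50, 60)]
        assert all(a >= b - 1e-12 for a, b in zip(etas, etas[1:]))
        assert etas[-1] < 0.1  # violent impact is lethal

    def test_soft_substrate_improves_survival(self):
        v0 = 15.0
        eta_hard = predict_single(CELL, 3 * CELL.diameter, v0, FLUID, HARD).eta
        eta_soft = predict_single(CELL, 3 * CELL.diameter, v0, FLUID, POOL).eta
        assert eta_soft >= eta_hard

    def test_droplet_must_contain_cell(self):
        with pytest.raises(ValueError):
            predict_single(CELL, 0.5 * CELL.diameter, 10.0, FLUID, HARD)

    def test_intermediates_are_consistent(self):
        out = predict_single(CELL, 39e-6, 10.0, FLUID, HARD)
        # volume conservation between final spreading and spheroid height
        assert out.spheroid_height * out.d_max_cell**2 == pytest.approx(
            CELL.diameter**3, rel=1e-12)
        assert out.m_cushioned <= out.m_bare
        assert out.d_max_cell <= min(out.d_max_cell_bare, out.d_max_droplet)
        assert 0.0 <= out.eta <= 1.0

    def test_low_weber_region_velocity_independent(self):
        # velocities whose cell Weber number stays below the threshold
        v_max = math.sqrt(5 * CELL.surface_tension / (CELL.density * CELL.diameter))
        etas = [predict_single(CELL, 39e-6, v, FLUID, HARD).eta
                for v in np.linspace(0, 0.99 * v_max, 20)]
        assert max(etas) - min(etas) < 1e-12

    def test_predict_eta_matches_scalar_chain(self):
        d0 = np.array([20e-6, 39e-6, 60e-6])
        v0 = np.array([5.0, 10.0, 20.0])
        vec = predict_eta(d0, v0)
        scal = [predict_single(CELL, d, v, FLUID, HARD).eta for d, v in zip(d0, v0)]
        np.testing.assert_allclose(vec, scal, rtol=1e-14)
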