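"""Physics kernel: friction, resistances, pressure drop, hysteresis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rhinoflow as rf
from rhinoflow.errors import InvalidParameterError, UndefinedFrictionError

# bounded, physically sensible parameter strategies
dh_st = st.floats(2e-3, 30e-3)
length_st = st.floats(0.01, 0.5)
q_st = st.floats(-1e-3, 1e-3)
qmax_st = st.floats(1e-5, 1.5e-3)
tau_st = st.floats(1.0, 20.0)


class TestReynolds:
    def test_zero_flow(self, duct_10mm, air):
        assert rf.reynolds_number(0.0, duct_10mm, air) == 0.0

    def test_reference_value(self, duct_10mm, air_rounded):
        # 4*600e-6 / (pi * 1.5e-5 * 0.01)
        re = rf.reynolds_number(600e-6, duct_10mm, air_rounded)
        assert re == pytest.approx(5.0930e3, rel=1e-4)

    def test_linear_in_flow(self, duct_10mm, air_rounded):
        re_full = rf.reynolds_number(600e-6, duct_10mm, air_rounded)
        re_half = rf.reynolds_number(300e-6, duct_10mm, air_rounded)
        assert re_half == pytest.approx(re_full / 2, rel=1e-12)

    def test_sign_independent(self, duct_10mm, air):
        assert rf.reynolds_number(-4e-4, duct_10mm, air) == rf.reynolds_number(
            4e-4, duct_10mm, air
        )


class TestFrictionFactor:
    @pytest.mark.parametrize(
        "re, eps, policy, expected",
        [
            (2000.0, 0.0, rf.LAMINAR, 64 / 2000),     # 64/Re at the laminar edge
            (4000.0, 0.0, rf.HAALAND, 0.040423),      # Haaland, smooth pipe
            (1e5, 0.0, rf.HAALAND, 0.017825),         # Haaland, smooth pipe
        ],
    )
    def test_branch_values(self, re, eps, policy, expected):
        assert rf.friction_factor(re, eps, policy) == pytest.approx(expected, rel=1e-4)

    def test_haaland_matches_colebrook_smooth_pipe(self):
        """Haaland approximates the implicit Colebrook equation closely."""
        from scipy.optimize import brentq

        re = 1e5
        colebrook = brentq(
            lambda f: 1 / math.sqrt(f) + 2.0 * math.log10(2.51 / (re * math.sqrt(f))),
            1e-4, 0.1, xtol=1e-14,
        )
        assert rf.haaland_friction_factor(re) == pytest.approx(colebrook, rel=0.02)

    def test_blend_coincides_with_pure_branches_outside_band(self):
        for re in (100.0, 500.0, 2000.0):
            assert rf.friction_factor(re, 0.0, rf.BLENDED) == pytest.approx(
                64 / re, rel=1e-12
            )
        for re in (4000.0, 1e4, 1e6):
            assert rf.friction_factor(re, 0.0, rf.BLENDED) == pytest.approx(
                rf.haaland_friction_factor(re), rel=1e-12
            )

    def test_blend_continuous_in_re(self):
        # a relative step of 1e-6 in Re moves fD by O(1e-6) everywhere,
        # including across the 2000/4000 blend edges
        re = np.logspace(0, 6, 2000)
        re = np.concatenate([re, [1999.999, 2000.001, 3999.999, 4000.001]])
        fd = rf.friction_factor(re, 0.0, rf.BLENDED)
        fd_eps = rf.friction_factor(re * (1 + 1e-6), 0.0, rf.BLENDED)
        assert np.max(np.abs(fd_eps - fd) / fd) < 1e-4

    def test_blend_weight_contract(self):
        pol = rf.BLENDED
        assert pol.wt(2000.0) == pytest.approx(1.0)
        assert pol.wt(4000.0) == pytest.approx(0.0, abs=1e-15)
        res = np.linspace(2000, 4000, 500)
        w = pol.wt(res)
        assert np.all(np.diff(w) <= 1e-12)  # monotone non-increasing

    def test_zero_re_raises(self):
        with pytest.raises(UndefinedFrictionError):
            rf.friction_factor(0.0, 0.0, rf.LAMINAR)
        with pytest.raises(UndefinedFrictionError):
            rf.friction_factor(0.0, 0.0, rf.BLENDED)

    def test_negative_roughness_rejected(self):
        with pytest.raises(InvalidParameterError):
            rf.haaland_friction_factor(1e5, -0.01)


class TestHagenPoiseuille:
    def test_zero_length(self, air):
        assert rf.hagen_poiseuille_resistance(rf.DuctModel(10e-3, 0.0), air) == 0.0

    def test_reference_value(self, duct_10mm, air):
        # 128 * 0.1 * 1.7894e-5 / (pi * (1e-2)^4)
        assert rf.hagen_poiseuille_resistance(duct_10mm, air) == pytest.approx(
            7.2907e3, rel=1e-4
        )

    def test_quartic_scaling(self, air):
        r1 = rf.hagen_poiseuille_resistance(rf.DuctModel(5e-3, 0.1), air)
        r2 = rf.hagen_poiseuille_resistance(rf.DuctModel(10e-3, 0.1), air)
        assert r1 == pytest.approx(16 * r2, rel=1e-12)

    def test_invalid_dh(self, air):
        with pytest.raises(InvalidParameterError):
            rf.DuctModel(0.0, 0.1)


class TestCombineResistances:
    @pytest.mark.parametrize("rl, rr, expected", [(2, 2, 1), (3, 6, 2)])
    def test_parallel_combination(self, rl, rr, expected):
        assert rf.combine_unilateral_resistances(rl, rr) == pytest.approx(expected)

    def test_occluded_side(self):
        assert rf.combine_unilateral_resistances(7.5, None) == 7.5
        assert rf.combine_unilateral_resistances(None, 7.5) == 7.5

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            rf.combine_unilateral_resistances(0.0, 1.0)
        with pytest.raises(InvalidParameterError):
            rf.combine_unilateral_resistances(None, None)

    @given(rl=st.floats(1e-3, 1e6), rr=st.floats(1e-3, 1e6))
    def test_symmetric_and_below_min(self, rl, rr):
        r = rf.combine_unilateral_resistances(rl, rr)
        assert r == rf.combine_unilateral_resistances(rr, rl)
        assert r <= min(rl, rr) * (1 + 1e-12)


class TestPressureDrop:
    def test_steady_laminar_reference(self, duct_10mm, air):
        dp = rf.pressure_drop(100e-6, 0.0, duct_10mm, air, rf.LAMINAR)
        assert dp == pytest.approx(0.7291, rel=1e-3)
        assert dp == pytest.approx(
            rf.hagen_poiseuille_resistance(duct_10mm, air) * 100e-6, rel=1e-12
        )

    def test_unsteady_only_is_half_width(self, duct_10mm, air, sine_protocol):
        omega = sine_protocol.angular_frequency
        dp = rf.pressure_drop(
            0.0, omega * sine_protocol.peak_flowrate, duct_10mm, air, rf.LAMINAR
        )
        w = rf.hysteresis_width(duct_10mm, air, sine_protocol)
        assert dp == pytest.approx(1.176, rel=1e-3)
        assert 2 * dp == pytest.approx(w, rel=1e-12)

    @pytest.mark.parametrize("policy", [rf.LAMINAR, rf.HAALAND, rf.BLENDED])
    def test_steady_term_antisymmetric(self, policy, duct_10mm, air):
        q = 450e-6
        dp_pos = rf.pressure_drop(q, 0.0, duct_10mm, air, policy)
        dp_neg = rf.pressure_drop(-q, 0.0, duct_10mm, air, policy)
        assert dp_neg == pytest.approx(-dp_pos, rel=1e-12)
        assert dp_pos > 0

    def test_zero_flow_no_error_under_re_dependent_policy(self, duct_10mm, air):
        # friction term vanishes at Q=0; only the inertial term remains
        dp = rf.pressure_drop(0.0, 1e-3, duct_10mm, air, rf.BLENDED)
        assert dp == pytest.approx(
            rf.pressure_drop(0.0, 1e-3, duct_10mm, air, rf.LAMINAR), rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(q=q_st, dh=dh_st, length=length_st)
    def test_laminar_steady_limit_property(self, q, dh, length):
        """Steady laminar curves are the Hagen-Poiseuille line through 0."""
        duct = rf.DuctModel(dh, length)
        air = rf.AIR_STANDARD
        dp = rf.pressure_drop(q, 0.0, duct, air, rf.LAMINAR)
        assert dp == pytest.approx(
            rf.hagen_poiseuille_resistance(duct, air) * q, rel=1e-12, abs=1e-300
        )


class TestHysteresisWidth:
    def test_zero_amplitude(self, duct_10mm, air):
        protocol = rf.BreathingProtocol(peak_flowrate=0.0, period=5.0)
        assert rf.hysteresis_width(duct_10mm, air, protocol) == 0.0

    def test_reference_value(self, duct_10mm, air, sine_protocol):
        assert rf.hysteresis_width(duct_10mm, air, sine_protocol) == pytest.approx(
            2.352, rel=1e-3
        )

    @settings(max_examples=50, deadline=None)
    @given(dh=dh_st, length=length_st, qmax=qmax_st, tau=tau_st)
    def test_width_equals_twice_unsteady_drop(self, dh, length, qmax, tau):
        duct = rf.DuctModel(dh, length)
        protocol = rf.BreathingProtocol(peak_flowrate=qmax, period=tau)
        w = rf.hysteresis_width(duct, rf.AIR_STANDARD, protocol)
        dp0 = rf.pressure_drop(
            0.0, protocol.angular_frequency * qmax, duct, rf.AIR_STANDARD, rf.LAMINAR
        )
        assert w == pytest.approx(2 * dp0, rel=1e-12)


class TestRelativeWidth:
    def test_reference_value(self, air_rounded):
        assert rf.relative_hysteresis_width(10e-3, 5.0, air_rounded) == pytest.approx(
            0.5236, rel=1e-3
        )

    @settings(max_examples=50, deadline=None)
    @given(dh=dh_st, length=length_st, qmax=qmax_st, tau=tau_st)
    def test_algebraic_identity_with_width(self, dh, length, qmax, tau):
        """W_rel * (R_HP * Qmax) == W for any L, Qmax > 0."""
        air = rf.AIR_STANDARD
        duct = rf.DuctModel(dh, length)
        protocol = rf.BreathingProtocol(peak_flowrate=qmax, period=tau)
        w_rel = rf.relative_hysteresis_width(dh, tau, air)
        w = rf.hysteresis_width(duct, air, protocol)
        r_hp = rf.hagen_poiseuille_resistance(duct, air)
        assert w_rel * r_hp * qmax == pytest.approx(w, rel=1e-10)


class TestWomersley:
    def test_zero_frequency(self, air_rounded):
        assert rf.womersley_number(5e-3, 0.0, air_rounded) == 0.0

    def test_nasal_order_of_magnitude(self, air_rounded):
        """Dh=5 mm at f=0.2 Hz gives Wo ~ 1: borderline quasi-steady."""
        wo = rf.womersley_number(5e-3, 0.2, air_rounded)
        assert wo == pytest.approx(0.7236, rel=1e-3)
        assert 0.5 <= wo <= 1.0

    def test_sqrt_scaling(self, air_rounded):
        wo1 = rf.womersley_number(5e-3, 0.2, air_rounded)
        wo4 = rf.womersley_number(5e-3, 0.8, air_rounded)
        assert wo4 == pytest.approx(2 * wo1, rel=1e-12)


class TestDimensionalScaling:
    """Dimensionless outputs are invariant under unit-consistent rescaling."""

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.1, 10.0),
        dh=dh_st,
        qmax=qmax_st,
        tau=tau_st,
    )
    def test_rescaling_lengths_and_times(self, scale, dh, qmax, tau):
        # rescale length by s and time by s: nu ~ L^2/T scales by s,
        # Q ~ L^3/T scales by s^2, f by 1/s
        air = rf.AIR_STANDARD
        air2 = rf.FluidProperties(air.density, air.dynamic_viscosity * scale)
        d1 = rf.DuctModel(dh, 0.1)
        d2 = rf.DuctModel(dh * scale, 0.1 * scale)
        re1 = rf.reynolds_number(qmax, d1, air)
        re2 = rf.reynolds_number(qmax * scale**2, d2, air2)
        assert re2 == pytest.approx(re1, rel=1e-10)
        wo1 = rf.womersley_number(dh, 1 / tau, air)
        wo2 = rf.womersley_number(dh * scale, 1 / (tau * scale), air2)
        assert wo2 == pytest.approx(wo1, rel=1e-10)
        wr1 = rf.relative_hysteresis_width(dh, tau, air)
        wr2 = rf.relative_hysteresis_width(dh * scale, tau * scale, air2)
        assert wr2 == pytest.approx(wr1, rel=1e-10)


class TestDomainTypes:
    def test_kinematic_viscosity_identity(self):
        f = rf.FluidProperties(1.2, 1.8e-5)
        assert f.kinematic_viscosity * f.density == pytest.approx(
            f.dynamic_viscosity, rel=1e-12
        )

    def test_presets(self):
        assert rf.AIR_STANDARD.density == 1.225
        assert rf.AIR_STANDARD.dynamic_viscosity == 1.7894e-5
        assert rf.AIR_ROUNDED_NU.kinematic_viscosity == pytest.approx(1.5e-5, rel=1e-12)

    def test_duct_from_cross_section(self):
        r = 7e-3
        duct = rf.DuctModel.from_cross_section(
            area=math.pi * r**2, perimeter=2 * math.pi * r, length=0.1
        )
        assert duct.hydraulic_diameter == pytest.approx(2 * r, rel=1e-12)

    def test_invalid_fluid(self):
        with pytest.raises(InvalidParameterError):
            rf.FluidProperties(-1.0, 1.8e-5)
        with pytest.raises(InvalidParameterError):
            rf.FluidProperties(1.2, 0.0)

    def test_invalid_blend_bounds(self):
        with pytest.raises(InvalidParameterError):
            rf.FrictionPolicy(blend_lower=4000, blend_upper=2000)
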