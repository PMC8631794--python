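"""Gating functions, per-channel currents, and the ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scnmodel.model_core import (ACTIVATION_EXPONENTS, ContractError,
                                 DomainError, GateKinetics, ModelParameters,
                                 ModelState, SynapticDrive, gate_steady_state,
                                 gate_time_constant, make_fast_rhs,
                                 membrane_currents, rhs, state_to_array,
                                 steady_gates_at)

ACT = GateKinetics(-35.0, 9.0, 1.0, 2.0)
INACT = GateKinetics(-50.0, -8.0, 5.0, 10.0)


class TestGateSteadyState:
    def test_midpoint_is_half(self):
        assert gate_steady_state(ACT.v_half, ACT) == pytest.approx(0.5)
        assert gate_steady_state(INACT.v_half, INACT) == pytest.approx(0.5)

    def test_saturation_ten_widths_out(self):
        assert gate_steady_state(ACT.v_half + 10 * abs(ACT.dv), ACT) > 0.999
        assert gate_steady_state(INACT.v_half - 10 * abs(INACT.dv), INACT) > 0.999

    @given(st.floats(-120, 40), st.floats(-120, 40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, v1, v2):
        lo, hi = sorted((v1, v2))
        a, b = gate_steady_state(lo, ACT), gate_steady_state(hi, ACT)
        assert 0.0 < a < 1.0 and 0.0 < b < 1.0
        assert a <= b  # increasing for dv > 0
        ai, bi = gate_steady_state(lo, INACT), gate_steady_state(hi, INACT)
        assert ai >= bi  # decreasing for dv < 0

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(DomainError):
            gate_steady_state(float("nan"), ACT)


class TestGateTimeConstant:
    def test_peak_at_center(self):
        assert gate_time_constant(ACT.v_half, ACT) == pytest.approx(ACT.tau0 + ACT.tau1)

    def test_tails_approach_tau0(self):
        far = gate_time_constant(ACT.v_half + 10 * abs(ACT.dv), ACT)
        assert far == pytest.approx(ACT.tau0, rel=1e-6)

    @given(st.floats(0, 60))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_about_center(self, x):
        left = gate_time_constant(ACT.v_half - x, ACT)
        right = gate_time_constant(ACT.v_half + x, ACT)
        assert left == pytest.approx(right, rel=1e-12)

    def test_scale_factor_multiplies(self):
        assert gate_time_constant(-50.0, INACT, sf=2.5) == pytest.approx(
            2.5 * gate_time_constant(-50.0, INACT))

    def test_instantaneous_gate_has_no_tau(self):
        inst = GateKinetics(-35.0, 9.0, instantaneous=True)
        with pytest.raises(ContractError):
            gate_time_constant(-40.0, inst)

    def test_tau_override_center(self):
        k = GateKinetics(-50.0, -8.0, 5.0, 10.0, v_half_tau=-60.0, dv_tau=6.0)
        assert gate_time_constant(-60.0, k) == pytest.approx(15.0)
        assert gate_time_constant(-50.0, k) < 15.0


class TestKineticsInvariants:
    def test_zero_dv_rejected(self):
        with pytest.raises(ValueError):
            GateKinetics(-35.0, 0.0)

    def test_negative_tau_profile_rejected(self):
        with pytest.raises(ValueError):
            GateKinetics(-35.0, 9.0, tau0=1.0, tau1=-2.0)

    def test_negative_tau1_allowed_if_positive_everywhere(self):
        k = GateKinetics(-35.0, 9.0, tau0=140.0, tau1=-139.0)
        assert gate_time_constant(k.v_half, k) == pytest.approx(1.0)


class TestMembraneCurrents:
    def test_reversal_potentials_zero_current(self, spiking_cell):
        p = spiking_cell
        st_ = steady_gates_at(p.E_Na, p)
        cur = membrane_currents(st_, p)
        assert cur.I_Na == 0.0
        assert cur.I_LNa == 0.0

    def test_inward_sign_convention(self, spiking_cell):
        st_ = steady_gates_at(-20.0, spiking_cell)
        cur = membrane_currents(st_, spiking_cell)
        assert cur.I_Na < 0      # below E_Na, open channel -> inward
        assert cur.I_K > 0       # above E_K -> outward
        assert cur.G_Na >= 0 and cur.G_K >= 0

    def test_zero_A_conductance_or_scale(self, spiking_cell):
        p = spiking_cell.with_(g_A=4.0, sf_gA=0.0)
        st_ = steady_gates_at(-40.0, p)
        st_.hA = 0.8
        cur = membrane_currents(st_, p)
        assert cur.I_A == 0.0 and cur.G_A == 0.0
        cur2 = membrane_currents(st_, spiking_cell.with_(g_A=0.0, sf_gA=1.0))
        assert cur2.I_A == 0.0

    def test_activation_exponents_enter_currents(self, spiking_cell):
        # doubling n must scale I_K by 2**exponent, asserting the table is live
        p = spiking_cell
        s1 = steady_gates_at(-30.0, p)
        s2 = ModelState(**{**s1.__dict__})
        s2.n = min(1.0, 2 * s1.n)
        ratio = membrane_currents(s2, p).I_K / membrane_currents(s1, p).I_K
        assert ratio == pytest.approx((s2.n / s1.n) ** ACTIVATION_EXPONENTS["n"])

    def test_leak_scale_factor_direction(self, spiking_cell):
        st_ = steady_gates_at(-50.0, spiking_cell)
        night = spiking_cell.with_(sf_leak=1.1)
        c0 = membrane_currents(st_, spiking_cell)
        c1 = membrane_currents(st_, night)
        assert c1.I_LK == pytest.approx(1.1 * c0.I_LK)
        assert c1.I_LNa == pytest.approx(c0.I_LNa / 1.1)

    def test_synaptic_currents_gate_on_s(self, spiking_cell):
        p = spiking_cell.with_(g_synI=18.0, g_synE=9.0)
        st_ = steady_gates_at(-50.0, p)
        c = membrane_currents(st_, p, s_E=0.5, s_I=0.5)
        assert c.I_synE == pytest.approx(9.0 * 0.5 * (-50.0 - p.E_synE))
        assert c.I_synI == pytest.approx(18.0 * 0.5 * (-50.0 - p.E_synI))
        c0 = membrane_currents(st_, p)  # absent drive = s == 0
        assert c0.I_synE == 0.0 and c0.I_synI == 0.0


class TestRhs:
    def test_conservation_identity(self, spiking_cell):
        # C dV/dt + sum(I) - I_app = 0 at an arbitrary state
        p = spiking_cell
        st_ = steady_gates_at(-47.3, p)
        st_.n = 0.21
        deriv = rhs(0.0, st_, p, I_app=12.5)
        total = membrane_currents(st_, p).total
        assert p.C * deriv[0] + total - 12.5 == pytest.approx(0.0, abs=1e-10)

    def test_single_leak_relaxes_to_EK(self):
        p = ModelParameters(g_Na=0.0, g_K=0.0, g_Ca=0.0, g_LNa=0.0, g_LK=0.4)
        st_ = steady_gates_at(-40.0, p)
        deriv = rhs(0.0, st_, p)
        expected = -p.g_LK * (-40.0 - p.E_K) / p.C
        assert deriv[0] == pytest.approx(expected)

    def test_nonfinite_inputs_rejected(self, spiking_cell):
        st_ = steady_gates_at(-50.0, spiking_cell)
        with pytest.raises(DomainError):
            rhs(0.0, st_, spiking_cell, I_app=float("inf"))

    def test_extended_equals_basic_when_H_A_zero(self, spiking_cell):
        p_ext = spiking_cell.with_(g_H=0.0, g_A=0.0)
        st_ = steady_gates_at(-52.0, p_ext)
        st_.mH, st_.hA = 0.3, 0.7  # nonzero states must not leak into currents
        d_ext = rhs(0.0, st_, p_ext, 5.0)
        d_basic = rhs(0.0, st_, spiking_cell.with_(g_H=0.0, g_A=0.0), 5.0)
        np.testing.assert_array_equal(d_ext[0], d_basic[0])

    def test_unity_scale_factors_are_identity(self, spiking_cell):
        p = spiking_cell
        assert p.g_A_eff == p.sf_gA * p.g_A
        q = p.with_(sf_leak=1.0, sf_gA=1.0, sf_tau_hA=1.0)
        st_ = steady_gates_at(-48.0, p)
        np.testing.assert_array_equal(rhs(0.0, st_, p, 3.0), rhs(0.0, st_, q, 3.0))

    def test_fast_rhs_matches_reference(self, spiking_cell):
        p = spiking_cell.with_(g_A=3.0, g_H=0.5)
        st_ = steady_gates_at(-44.0, p)
        st_.hNa, st_.hA = 0.42, 0.61
        ref = rhs(2.0, st_, p, I_app=-7.5)
        fast = make_fast_rhs(p)(2.0, state_to_array(st_), -7.5)
        np.testing.assert_allclose(np.asarray(fast), ref, rtol=1e-12, atol=1e-15)


class TestParameterInvariants:
    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(g_Na=-1.0)

    def test_reversal_ordering_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(E_Na=-100.0, E_K=-20.0)

    def test_gating_fraction_bounds(self):
        with pytest.raises(ValueError):
            ModelState(V=-50.0, hNa=1.2, n=0.0, mCa=0.0, hCa=0.0)


class TestSynapticDrive:
    def test_bounds_and_monotone_time_enforced(self):
        with pytest.raises(ValueError):
            SynapticDrive(np.array([0.0, 1.0]), np.array([0.0, 1.5]))
        with pytest.raises(ValueError):
            SynapticDrive(np.array([1.0, 0.0]), np.array([0.0, 0.5]))

    def test_hold_previous_vs_linear(self):
        t = np.array([0.0, 10.0])
        s = np.array([0.0, 1.0])
        assert SynapticDrive(t, s, "previous")(5.0) == 0.0
        assert SynapticDrive(t, s, "linear")(5.0) == pytest.approx(0.5)
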