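"""Integrator correctness, resting-behavior classification, spike detection, f-I."""

import numpy as np
import pytest

from scnmodel.model_core import ModelParameters, steady_gates_at
from scnmodel.simulation import (SolverOptions, SpikeCriteria, StimulusProtocol,
                                 detect_spikes, fI_curve, find_resting_behavior,
                                 integrate)
from conftest import make_spike_train_trace


class TestStimulusProtocol:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusProtocol("bad", 0.0, ((0.0, 100.0, 10.0), (50.0, 100.0, 5.0)), 500.0)

    def test_segment_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol("bad", 0.0, ((400.0, 200.0, 10.0),), 500.0)

    def test_current_samples_match_pointwise(self):
        proto = StimulusProtocol("p", -2.0, ((100.0, 50.0, 30.0),), 300.0)
        t = np.array([0.0, 99.9, 100.0, 149.9, 150.0, 299.0])
        expected = [proto.current_at(x) for x in t]
        np.testing.assert_array_equal(proto.current_samples(t), expected)


class TestIntegrate:
    def test_passive_rc_charging_matches_closed_form(self, passive_cell):
        """A leak-only cell under a -30 pA step is an exact RC circuit."""
        p = passive_cell
        g = p.g_LNa + p.g_LK
        V_rest = (p.g_LNa * p.E_Na + p.g_LK * p.E_K) / g
        tau = p.C / g
        proto = StimulusProtocol.single_pulse(-30.0, 100.0, 500.0, 700.0)
        trace = integrate(p, proto, steady_gates_at(V_rest, p))
        m = (trace.t_ms >= 100.0) & (trace.t_ms <= 600.0)
        t_rel = trace.t_ms[m] - 100.0
        V_inf = V_rest - 30.0 / g
        expected = V_inf + (V_rest - V_inf) * np.exp(-t_rel / tau)
        err = np.abs(trace.V_mV[m] - expected) / np.abs(V_inf - V_rest)
        assert err.max() < 1e-3  # 0.1 % of the step amplitude

    def test_equilibrium_persists(self, passive_cell):
        rb = find_resting_behavior(passive_cell, 0.0, settle_ms=2000.0)
        assert rb.mode == "fixed-point"
        proto = StimulusProtocol.constant(0.0, 2000.0)
        trace = integrate(passive_cell, proto, rb.state)
        assert np.abs(trace.V_mV - rb.state.V).max() < 0.01

    def test_deterministic(self, spiking_cell):
        proto = StimulusProtocol.single_pulse(30.0, 100.0, 200.0, 400.0)
        init = steady_gates_at(-55.0, spiking_cell)
        a = integrate(spiking_cell, proto, init)
        b = integrate(spiking_cell, proto, init)
        np.testing.assert_array_equal(a.V_mV, b.V_mV)

    def test_split_and_resume_reproduces_unsplit(self, spiking_cell):
        init = steady_gates_at(-55.0, spiking_cell)
        whole = integrate(spiking_cell, StimulusProtocol.constant(0.0, 600.0), init)
        first = integrate(spiking_cell, StimulusProtocol.constant(0.0, 350.0), init)
        second = integrate(spiking_cell, StimulusProtocol.constant(0.0, 250.0),
                           first.meta["final_state"])
        stitched = np.concatenate([first.V_mV[:-1], second.V_mV])
        np.testing.assert_allclose(stitched, whole.V_mV, atol=5e-3)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_failure_carries_last_valid_time(self, passive_cell):
        # unattainable tolerances make the solver report failure
        from scnmodel.simulation import IntegrationError
        proto = StimulusProtocol.constant(0.0, 100.0)
        with pytest.raises(IntegrationError) as err:
            integrate(passive_cell, proto, steady_gates_at(-50.0, passive_cell),
                      SolverOptions(rtol=1e-38, atol=1e-40))
        assert err.value.last_valid_time >= 0.0


class TestDetectSpikes:
    def test_constant_trace_has_no_spikes(self):
        tr = make_spike_train_trace([], duration_ms=1000.0)
        assert detect_spikes(tr).count == 0

    def test_constructed_train_detected_exactly(self):
        times = [100.0, 300.0, 450.0, 700.0, 1100.0, 1500.0, 1900.0]
        tr = make_spike_train_trace(times, duration_ms=2000.0, dt_ms=0.1)
        sp = detect_spikes(tr)
        assert sp.count == 7
        np.testing.assert_allclose(sp.times_ms, times, atol=0.1)

    def test_refractory_merges_double_crossings(self):
        tr = make_spike_train_trace([100.0, 100.8], duration_ms=500.0, dt_ms=0.1)
        assert detect_spikes(tr, SpikeCriteria(refractory_ms=2.0)).count == 1

    def test_subthreshold_oscillation_no_spikes(self):
        # DLAMO-like 5 mV oscillation never crosses -20 mV
        t = np.arange(0, 10_000.0, 0.5)
        V = -35.0 + 2.5 * np.sin(2 * np.pi * t / 250.0)
        from scnmodel.simulation import SimulatedTrace
        tr = SimulatedTrace(t, V, np.zeros_like(t))
        assert detect_spikes(tr).count == 0

    def test_count_invariant_to_sampling_rate(self, spiking_cell):
        init = steady_gates_at(-55.0, spiking_cell)
        proto = StimulusProtocol.constant(0.0, 1500.0)
        counts = []
        for dt in (0.04, 0.1):  # 25 kHz and 10 kHz
            tr = integrate(spiking_cell, proto, init, SolverOptions(output_dt_ms=dt))
            counts.append(detect_spikes(tr).count)
        assert counts[0] == counts[1]


class TestRestingBehavior:
    def test_all_leak_cell_rests_at_weighted_reversal(self, passive_cell):
        rb = find_resting_behavior(passive_cell, 0.0, settle_ms=2000.0)
        g = passive_cell.g_LNa + passive_cell.g_LK
        expected = (passive_cell.g_LNa * passive_cell.E_Na
                    + passive_cell.g_LK * passive_cell.E_K) / g
        assert rb.mode == "fixed-point"
        assert rb.state.V == pytest.approx(expected, abs=1e-6)

    def test_fixed_point_satisfies_rhs(self, passive_cell):
        from scnmodel.model_core import make_fast_rhs, state_to_array
        rb = find_resting_behavior(passive_cell, -10.0, settle_ms=2000.0)
        f = make_fast_rhs(passive_cell)
        resid = np.linalg.norm(f(0.0, state_to_array(rb.state), -10.0))
        assert resid < 1e-6

    def test_spontaneous_firing_cell_oscillates(self, spiking_cell):
        rb = find_resting_behavior(spiking_cell, 0.0)
        assert rb.mode == "oscillating"
        assert rb.rate_hz > 1.0
        assert rb.period_ms == pytest.approx(1000.0 / rb.rate_hz, rel=0.2)

    def test_strong_potassium_leak_hyperpolarizes(self, spiking_cell):
        p = spiking_cell.with_(g_LK=3.0)
        rb = find_resting_behavior(p, 0.0)
        assert rb.mode == "fixed-point"
        assert rb.state.V < -50.0


class TestFICurve:
    def test_far_below_rheobase_is_silent(self, spiking_cell):
        out = fI_curve(spiking_cell, [-30.0], discard_ms=1000.0, window_ms=2000.0)
        assert out[0]["rate_hz"] == 0.0

    def test_zero_current_rate_matches_spontaneous(self, spiking_cell):
        rb = find_resting_behavior(spiking_cell, 0.0)
        out = fI_curve(spiking_cell, [0.0], discard_ms=2000.0, window_ms=4000.0)
        assert out[0]["rate_hz"] == pytest.approx(rb.rate_hz, rel=0.05)

    def test_monotone_rise_over_moderate_range(self, spiking_cell):
        amps = [-10.0, 0.0, 10.0]
        rates = [r["rate_hz"] for r in
                 fI_curve(spiking_cell, amps, discard_ms=2000.0, window_ms=3000.0)]
        assert rates == sorted(rates)


class TestSolverAccuracy:
    def test_tolerance_halving_leaves_spike_times(self, spiking_cell):
        """Spike times over 5 s move < 0.1 ms when tolerances are halved."""
        init = steady_gates_at(-55.0, spiking_cell)
        proto = StimulusProtocol.constant(0.0, 5_000.0)
        t1 = detect_spikes(integrate(spiking_cell, proto, init,
                                     SolverOptions(rtol=1e-8, atol=1e-10))).times_ms
        t2 = detect_spikes(integrate(spiking_cell, proto, init,
                                     SolverOptions(rtol=5e-9, atol=5e-11))).times_ms
        assert t1.size == t2.size
        assert np.abs(t1 - t2).max() < 0.1

    def test_gating_stays_in_bounds(self, spiking_cell):
        init = steady_gates_at(-80.0, spiking_cell)
        tr = integrate(spiking_cell, StimulusProtocol.constant(20.0, 2000.0),
                       init, store_gates=True)
        for name, q in tr.gates.items():
            assert q.min() >= 0.0 and q.max() <= 1.0, name

    def test_phase_plot_uses_rhs(self, spiking_cell):
        init = steady_gates_at(-55.0, spiking_cell)
        tr = integrate(spiking_cell, StimulusProtocol.constant(0.0, 500.0),
                       init, store_gates=True)
        dv = tr.dVdt(spiking_cell)
        # compare against a central finite difference only in smooth regions
        fd = np.gradient(tr.V_mV, tr.t_ms)
        smooth = np.abs(fd) < 1.0
        assert np.median(np.abs(dv[smooth] - fd[smooth])) < 0.05
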