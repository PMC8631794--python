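"""Passive properties and evoked-response classification on constructed traces."""

import numpy as np
import pytest

from scnmodel.features import (FeatureConfig, classify_depolarizing_response,
                               classify_electrical_state, measure_delay_to_fire,
                               measure_input_resistance, measure_rmp_sfr)
from scnmodel.model_core import steady_gates_at
from scnmodel.simulation import (SimulatedTrace, StimulusProtocol, integrate)
from conftest import make_flat_trace, make_spike_train_trace


class TestRmpSfr:
    def test_silent_trace(self):
        rmp, sfr = measure_rmp_sfr(make_flat_trace(V=-50.0))
        assert rmp == pytest.approx(-50.0)
        assert sfr == 0.0

    def test_regular_two_hz_train_exact(self):
        times = np.arange(250.0, 30_000.0, 500.0)  # 2 Hz over the window
        tr = make_spike_train_trace(times, duration_ms=30_000.0, dt_ms=0.5)
        _, sfr = measure_rmp_sfr(tr, window_ms=30_000.0)
        assert sfr == pytest.approx(2.0)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            measure_rmp_sfr(make_flat_trace(duration_ms=10_000.0), window_ms=30_000.0)

    def test_nonconstant_current_rejected(self):
        tr = make_flat_trace(duration_ms=35_000.0)
        tr.I_app_pA[-100:] = 5.0
        with pytest.raises(ValueError, match="constant"):
            measure_rmp_sfr(tr)

    def test_spike_masked_rmp_below_inclusive(self):
        times = np.arange(250.0, 30_000.0, 250.0)
        tr = make_spike_train_trace(times, duration_ms=30_000.0, dt_ms=0.5,
                                    baseline=-50.0, peak=10.0)
        rmp_incl, _ = measure_rmp_sfr(tr)
        rmp_masked, _ = measure_rmp_sfr(tr, mask_spikes=True)
        assert rmp_incl > rmp_masked  # spikes pull the inclusive mean up
        assert rmp_masked == pytest.approx(-50.0)


class TestInputResistance:
    @staticmethod
    def _pulse_proto():
        return StimulusProtocol("r_input", 0.0, ((500.0, 500.0, -30.0),), 1500.0)

    def test_pure_resistor_two_gigaohm(self):
        proto = self._pulse_proto()
        t = np.arange(0.0, 1500.0, 0.5)
        V = np.where((t >= 500.0) & (t < 1000.0), -110.0, -50.0)  # dV = -60 mV
        tr = SimulatedTrace(t, V, proto.current_samples(t), protocol=proto)
        pp = measure_input_resistance(tr)
        assert pp.R_input_GOhm == pytest.approx(2.0)
        assert not pp.flags

    def test_passive_cell_matches_inverse_leak(self, passive_cell):
        proto = self._pulse_proto()
        from scnmodel.simulation import find_resting_behavior
        rb = find_resting_behavior(passive_cell, 0.0, settle_ms=2000.0)
        tr = integrate(passive_cell, proto, rb.state)
        pp = measure_input_resistance(tr)
        expected = 1.0 / (passive_cell.g_LNa + passive_cell.g_LK)
        assert pp.R_input_GOhm == pytest.approx(expected, rel=0.01)

    def test_amplitude_independence_on_linear_cell(self, passive_cell):
        from scnmodel.simulation import find_resting_behavior
        rb = find_resting_behavior(passive_cell, 0.0, settle_ms=2000.0)
        values = []
        for amp in (-10.0, -30.0):
            proto = StimulusProtocol("r", 0.0, ((500.0, 500.0, amp),), 1500.0)
            tr = integrate(passive_cell, proto, rb.state)
            values.append(measure_input_resistance(tr).R_input_GOhm)
        assert values[0] == pytest.approx(values[1], rel=1e-3)

    def test_depolarizing_pulse_rejected(self):
        proto = StimulusProtocol("bad", 0.0, ((500.0, 500.0, 30.0),), 1500.0)
        t = np.arange(0.0, 1500.0, 0.5)
        tr = SimulatedTrace(t, np.full(t.size, -50.0), proto.current_samples(t),
                            protocol=proto)
        with pytest.raises(ValueError, match="hyperpolarizing"):
            measure_input_resistance(tr)


def _pulse_trace(spike_times, amp, duration=4000.0, onset=1000.0, width=1000.0,
                 baseline=-50.0):
    proto = StimulusProtocol("p", 0.0, ((onset, width, amp),), duration)
    return make_spike_train_trace(spike_times, duration_ms=duration, dt_ms=0.2,
                                  baseline=baseline, protocol=proto)


class TestDepolarizingClassification:
    def test_regular_train_nonadapting(self):
        times = np.arange(1050.0, 2000.0, 100.0)
        ev = classify_depolarizing_response(_pulse_trace(times, 30.0))
        assert ev.depolarizing_class == "non-adapting"
        assert ev.evidence["rate_ratio"] >= 0.75

    def test_spikes_only_first_300ms_is_adapting_to_silent(self):
        times = [1020.0, 1100.0, 1180.0, 1260.0]
        ev = classify_depolarizing_response(_pulse_trace(times, 30.0))
        assert ev.depolarizing_class == "adapting-to-silent"

    def test_slowing_train_is_adapting_firing(self):
        # decelerating but still firing in the final 500 ms
        times = [1020.0, 1080.0, 1150.0, 1240.0, 1360.0, 1520.0, 1780.0]
        ev = classify_depolarizing_response(_pulse_trace(times, 30.0))
        assert ev.depolarizing_class == "adapting-firing"

    def test_no_spikes_flagged_unclassifiable(self):
        ev = classify_depolarizing_response(_pulse_trace([], 30.0))
        assert ev.depolarizing_class is None
        assert any("unclassifiable" in f for f in ev.flags)


class TestDelayToFire:
    def _trace_with_rebound(self, latency_ms, dip_mV=None):
        # firing before the pulse, silent during, resumes after offset+latency
        pre = list(np.arange(100.0, 1000.0, 200.0))
        post = list(np.arange(2000.0 + latency_ms, 4000.0, 200.0))
        tr = _pulse_trace(pre + post, -30.0)
        m = (tr.t_ms >= 1000.0) & (tr.t_ms < 2000.0)
        tr.V_mV[m] = -75.0  # hyperpolarized during pulse
        if dip_mV is not None:
            dip = (tr.t_ms >= 2002.0) & (tr.t_ms < 2000.0 + latency_ms - 5.0)
            tr.V_mV[dip] = dip_mV
        return tr

    def test_short_latency_is_type_A(self):
        ev = measure_delay_to_fire(self._trace_with_rebound(30.0))
        assert ev.hyperpolarizing_class == "type-A"
        assert ev.delay_latency_ms == pytest.approx(30.0, abs=1.0)
        assert ev.rebound_spike

    def test_long_latency_with_rebound_hyperpolarization_is_type_B(self):
        ev = measure_delay_to_fire(self._trace_with_rebound(600.0, dip_mV=-58.0))
        assert ev.hyperpolarizing_class == "type-B"
        assert ev.delay_latency_ms == pytest.approx(600.0, abs=1.0)

    def test_long_latency_without_dip_stays_type_A(self):
        ev = measure_delay_to_fire(self._trace_with_rebound(600.0))
        assert ev.hyperpolarizing_class == "type-A"

    def test_no_post_spike_flagged(self):
        pre = list(np.arange(100.0, 1000.0, 200.0))
        tr = _pulse_trace(pre, -30.0)
        ev = measure_delay_to_fire(tr)
        assert ev.delay_latency_ms is None
        assert any("latency undefined" in f for f in ev.flags)


class TestElectricalState:
    def test_flat_hyperpolarized(self):
        st = classify_electrical_state(make_flat_trace(V=-60.0, duration_ms=12_000.0))
        assert st.electrical_state == "hyperpolarized-silent"

    def test_flat_depolarized(self):
        st = classify_electrical_state(make_flat_trace(V=-30.0, duration_ms=12_000.0))
        assert st.electrical_state == "depolarized-silent"

    def test_sinusoid_is_dlamo(self):
        t = np.arange(0.0, 12_000.0, 1.0)
        V = -35.0 + 2.5 * np.sin(2 * np.pi * t / 300.0)  # 5 mV pp
        tr = SimulatedTrace(t, V, np.zeros_like(t))
        st = classify_electrical_state(tr)
        assert st.electrical_state == "DLAMO"
        assert st.dlamo

    def test_spiking_is_firing(self):
        times = np.arange(500.0, 12_000.0, 400.0)
        tr = make_spike_train_trace(times, duration_ms=12_000.0, dt_ms=0.5)
        assert classify_electrical_state(tr).electrical_state == "firing"

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            classify_electrical_state(make_flat_trace(duration_ms=5_000.0))
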