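"""Shared fixtures: small fast parameter sets and generated traces."""

import numpy as np
import pytest

from scnmodel.model_core import GateKinetics, ModelParameters
from scnmodel.simulation import SimulatedTrace, StimulusProtocol


@pytest.fixture(scope="session")
def passive_cell() -> ModelParameters:
    """Leak-only cell: every voltage-gated conductance zero (exact RC)."""
    return ModelParameters(C=5.7, g_Na=0.0, g_K=0.0, g_Ca=0.0,
                           g_LNa=0.2, g_LK=0.3)


@pytest.fixture(scope="session")
def spiking_cell() -> ModelParameters:
    """Small tonically firing cell used where any spiking model will do."""
    from scnmodel.fixtures import load_fixture
    return load_fixture("nonadapting")


def make_flat_trace(V: float = -50.0, duration_ms: float = 35_000.0,
                    dt_ms: float = 1.0, I: float = 0.0) -> SimulatedTrace:
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    proto = StimulusProtocol.constant(I, duration_ms)
    return SimulatedTrace(t, np.full(t.size, V), np.full(t.size, I),
                          protocol=proto)


def make_spike_train_trace(spike_times_ms, duration_ms: float = 35_000.0,
                           dt_ms: float = 0.1, baseline: float = -50.0,
                           peak: float = 10.0, width_ms: float = 2.0,
                           protocol: StimulusProtocol | None = None) -> SimulatedTrace:
    """Stereotyped triangular spikes at known times on a flat baseline."""
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    V = np.full(t.size, baseline)
    for ts in spike_times_ms:
        m = np.abs(t - ts - width_ms / 2) <= width_ms / 2
        V[m] = peak  # rectangular crossing is fine for threshold detection
    proto = protocol or StimulusProtocol.constant(0.0, duration_ms)
    return SimulatedTrace(t, V, proto.current_samples(t), protocol=proto)
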