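"""Synthetic protocols, noisy recordings, synaptic drives, and parameter populations.

Everything here is a pure function of its seed and specification, so every
other module is testable with no external data.  The standard protocol
library mirrors the classical current-clamp battery for SCN neurons:
depolarizing/hyperpolarizing steps from -30 to +30 pA in 5 pA increments
(1 s pulses), the -30 pA / 500 ms input-resistance pulse, and a steady-hold
series from 0 down to -16 pA that walks a hyperexcited cell through its
electrical states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import GateKinetics, ModelParameters, SynapticDrive
from .simulation import (SimulatedTrace, SolverOptions, StimulusProtocol,
                         find_resting_behavior, integrate)

__all__ = [
    "NoiseSpec",
    "PopulationSpec",
    "standard_protocols",
    "generate_recording",
    "generate_synaptic_gating",
    "make_population",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive iid Gaussian voltage noise (mV standard deviation), seeded."""

    sd_mV: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_mV < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """A population of cells drawn around a base parameter set.

    ``conductance_jitter`` gives (low, high) multiplicative uniform bounds
    applied to each maximal conductance; day cells receive sf_leak drawn
    below 1 (daytime up-state) and night cells above 1 (night-time
    down-state).
    """

    n_cells: int
    base: ModelParameters
    conductance_jitter: tuple[float, float] = (0.9, 1.1)
    day_fraction: float = 0.5
    sf_leak_day: tuple[float, float] = (0.90, 0.97)
    sf_leak_night: tuple[float, float] = (1.03, 1.10)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.conductance_jitter
        if not (0 < lo <= hi):
            raise ValueError("conductance jitter bounds must satisfy 0 < low <= high")
        if not (0.0 <= self.day_fraction <= 1.0):
            raise ValueError("day_fraction must lie in [0, 1]")
        for name, (a, b) in (("sf_leak_day", self.sf_leak_day),
                             ("sf_leak_night", self.sf_leak_night)):
            if not (0 < a <= b):
                raise ValueError(f"{name} bounds invalid")
        if not self.sf_leak_day[1] < 1.0 < self.sf_leak_night[0]:
            raise ValueError("day sf_leak must be < 1 and night sf_leak > 1")


def standard_protocols() -> dict[str, StimulusProtocol]:
    """Named library of the standard current-clamp protocols.

    Keys: ``step_{-30..+30}pA`` (1 s pulses at 5 pA spacing, 1 s pre and
    1 s post baseline), ``r_input`` (-30 pA, 500 ms), ``pulse_+30pA`` /
    ``pulse_-30pA`` aliases, and ``hold_{0..-16}pA`` steady holds.
    """
    lib: dict[str, StimulusProtocol] = {}
    for amp in range(-30, 31, 5):
        name = f"step_{amp:+d}pA"
        lib[name] = StimulusProtocol(name, 0.0, ((1000.0, 1000.0, float(amp)),), 3000.0)
    lib["pulse_+30pA"] = lib["step_+30pA"]
    lib["pulse_-30pA"] = lib["step_-30pA"]
    lib["r_input"] = StimulusProtocol("r_input", 0.0, ((500.0, 500.0, -30.0),), 1500.0)
    for hold in (0, -4, -8, -12, -16):
        name = f"hold_{hold:+d}pA"
        lib[name] = StimulusProtocol(name, float(hold), (), 12_000.0)
    return lib


def generate_recording(p: ModelParameters, proto: StimulusProtocol,
                       noise: NoiseSpec = NoiseSpec(),
                       options: SolverOptions = SolverOptions(),
                       init=None, settle: bool = True,
                       store_gates: bool = False) -> SimulatedTrace:
    """Integrate the model under a protocol and add seeded Gaussian noise to V.

    The clean trace is deterministic; noise with the same seed reproduces
    the identical recording.  Metadata records the true-parameter hash and
    the seed, supporting twin experiments.
    """
    if init is None and settle:
        rb = find_resting_behavior(p, proto.baseline_pA)
        init = rb.state if rb.mode == "fixed-point" else rb.cycle.meta["final_state"]
    trace = integrate(p, proto, init, options, store_gates=store_gates)
    V = trace.V_mV
    if noise.sd_mV > 0:
        rng = np.random.default_rng(noise.seed)
        V = V + rng.normal(0.0, noise.sd_mV, size=V.size)
    meta = dict(trace.meta)
    meta.update({"noise_sd_mV": noise.sd_mV, "noise_seed": noise.seed})
    return SimulatedTrace(trace.t_ms, V, trace.I_app_pA, trace.gates,
                          trace.currents, meta, trace.protocol)


def generate_synaptic_gating(rate_hz: float, tau_ms: float, duration_ms: float,
                             seed: int = 0, dt_ms: float = 1.0) -> SynapticDrive:
    """Poisson-event synaptic gating waveform s(t) in [0, 1].

    Each event adds a unit-amplitude instantaneous rise followed by
    exponential decay exp(-t/tau); the superposition is clipped at 1.
    A stand-in for gating waveforms derived from recorded post-synaptic
    currents, which are not tabulated anywhere reusable.
    """
    if rate_hz < 0:
        raise ValueError("event rate must be >= 0")
    if tau_ms <= 0:
        raise ValueError("decay tau must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    s = np.zeros_like(t)
    n_events = rng.poisson(rate_hz * duration_ms / 1000.0)
    events = np.sort(rng.uniform(0.0, duration_ms, size=n_events))
    for t0 in events:
        m = t >= t0
        s[m] += np.exp(-(t[m] - t0) / tau_ms)
    s = np.clip(s, 0.0, 1.0)
    drive = SynapticDrive(t, s, interpolation="linear")
    drive.event_times_ms = events  # type: ignore[attr-defined]
    return drive


def make_population(spec: PopulationSpec) -> list[ModelParameters]:
    """Seeded population of parameter sets with day/night sf_leak assignment."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.conductance_jitter
    n_day = int(round(spec.n_cells * spec.day_fraction))
    cells = []
    for i in range(spec.n_cells):
        changes = {}
        for gname in ("g_Na", "g_K", "g_Ca", "g_LNa", "g_LK", "g_H", "g_A"):
            changes[gname] = getattr(spec.base, gname) * rng.uniform(lo, hi)
        if i < n_day:
            changes["sf_leak"] = rng.uniform(*spec.sf_leak_day)
        else:
            changes["sf_leak"] = rng.uniform(*spec.sf_leak_night)
        cells.append(replace(spec.base, **changes))
    return cells
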