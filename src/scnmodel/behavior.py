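"""In-silico mechanism experiments on fitted SCN neuron models.

Sweeps that reproduce the model analyses around circadian excitability and
the A-type current: the leak-ratio ("bicycle") sweep across day/night
states, delay-to-fire latency as a function of A-conductance and
inactivation-time-constant scaling, in-silico A-current blockade (the 4-AP
experiment), firing-rate maps under GABAergic synaptic drive of either
polarity, and simulation-based classification of the onset of spiking
(continuous, supercritical-like versus abrupt/hysteretic,
subcritical-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FeatureConfig, classify_electrical_state, measure_delay_to_fire
from .model_core import ModelParameters, SynapticDrive
from .simulation import (SimulatedTrace, SolverOptions, StimulusProtocol,
                         detect_spikes, find_resting_behavior, integrate)

__all__ = [
    "SweepResult",
    "leak_scaling_sweep",
    "ia_latency_curves",
    "simulate_4AP",
    "synaptic_conductance_map",
    "spiking_onset_scan",
]

_FAST = SolverOptions(rtol=1e-6, atol=1e-8, output_dt_ms=0.1)


@dataclass
class SweepResult:
    """Grid sweep output: one record per grid point, plus provenance."""

    swept: tuple[str, ...]
    grid: list[tuple]
    records: list[dict]
    provenance: dict = field(default_factory=dict)

    def column(self, key: str) -> np.ndarray:
        return np.array([r.get(key, np.nan) for r in self.records], dtype=float)


def _spontaneous_record(p: ModelParameters, settle_ms: float, config: FeatureConfig) -> dict:
    """Resting-state label and firing rate at zero current."""
    rec: dict = {}
    try:
        rb = find_resting_behavior(p, 0.0, settle_ms=settle_ms,
                                   analysis_ms=min(4000.0, settle_ms / 2),
                                   options=_FAST)
    except Exception as err:
        return {"ok": False, "error": str(err)}
    rec["ok"] = True
    rec["rate_hz"] = rb.rate_hz
    if rb.mode == "fixed-point":
        v = rb.state.V
        rec["V_rest_mV"] = v
        rec["state"] = ("depolarized-silent" if v > config.depolarized_mean_mV
                        else "hyperpolarized-silent")
    else:
        rec["V_rest_mV"] = 0.5 * (rb.v_min + rb.v_max)
        if rb.rate_hz > config.firing_sfr_hz:
            rec["state"] = "firing"
        else:
            vpp = rb.v_max - rb.v_min
            vmean = rec["V_rest_mV"]
            if (config.dlamo_vpp_min_mV <= vpp <= config.dlamo_vpp_max_mV
                    and vmean > config.depolarized_mean_mV):
                rec["state"] = "DLAMO"
            elif vmean > config.depolarized_mean_mV:
                rec["state"] = "depolarized-silent"
            else:
                rec["state"] = "hyperpolarized-silent"
    return rec


def leak_scaling_sweep(p: ModelParameters,
                       sf_values: Sequence[float] = tuple(np.round(np.arange(0.85, 1.151, 0.025), 3)),
                       settle_ms: float = 10_000.0,
                       config: FeatureConfig = FeatureConfig()) -> SweepResult:
    """Sweep the potassium/sodium leak-ratio scaling factor (the circadian knob).

    sf < 1 divides g_LNa less / multiplies g_LK less -> daytime up-state;
    sf > 1 -> night-time down-state.  Each point reports the resting-state
    label and spontaneous firing rate.
    """
    records = []
    for sf in sf_values:
        q = p.with_(sf_leak=float(sf))
        rec = _spontaneous_record(q, settle_ms, config)
        rec["sf_leak"] = float(sf)
        rec["phase"] = "day-up" if sf < 1 else ("night-down" if sf > 1 else "nominal")
        records.append(rec)
    return SweepResult(("sf_leak",), [(float(s),) for s in sf_values], records,
                       provenance={"base": repr(p)})


_HYP_PULSE = StimulusProtocol("hyp_1s_-30pA", 0.0, ((2000.0, 1000.0, -30.0),), 8000.0)


def _latency_record(p: ModelParameters, config: FeatureConfig,
                    options: SolverOptions = _FAST) -> dict:
    """Delay-to-fire measurement under the standard 1 s -30 pA pulse."""
    try:
        rb = find_resting_behavior(p, 0.0, options=options)
        init = rb.state if rb.mode == "fixed-point" else rb.cycle.meta["final_state"]
        tr = integrate(p, _HYP_PULSE, init, options)
        ev = measure_delay_to_fire(tr, config)
    except Exception as err:
        return {"ok": False, "error": str(err)}
    rec = {"ok": True, "latency_ms": ev.delay_latency_ms,
           "class": ev.hyperpolarizing_class, "sag_mV": ev.sag_amplitude_mV,
           "flags": ev.flags}
    if ev.delay_latency_ms is None:
        rec["ok"] = False
        rec["error"] = "latency undefined"
    return rec


def ia_latency_curves(p: ModelParameters,
                      sf_gA_values: Sequence[float] = (0.0, 0.25, 0.5, 0.7, 1.0, 1.25, 1.5),
                      sf_tau_values: Sequence[float] = (1.0,),
                      config: FeatureConfig = FeatureConfig()) -> SweepResult:
    """Delay-to-fire latency over a grid of A-conductance and tau scalings.

    Expected directionality on a delay-type cell: latency non-decreasing in
    either scaling factor; zero A-conductance converts the response to
    rebound (Type-A) firing.
    """
    if p.g_A <= 0:
        raise ValueError("latency curves require a model with an A-type current")
    records = []
    grid = []
    for sf_t in sf_tau_values:
        for sf_g in sf_gA_values:
            q = p.with_(sf_gA=float(sf_g), sf_tau_hA=float(sf_t))
            rec = _latency_record(q, config)
            rec.update({"sf_gA": float(sf_g), "sf_tau_hA": float(sf_t)})
            records.append(rec)
            grid.append((float(sf_g), float(sf_t)))
    return SweepResult(("sf_gA", "sf_tau_hA"), grid, records,
                       provenance={"base": repr(p), "protocol": _HYP_PULSE.name})


def simulate_4AP(p: ModelParameters,
                 config: FeatureConfig = FeatureConfig()) -> dict:
    """In-silico A-channel blockade: compare latency with sf_gA = 1 vs 0.

    Mirrors bath application of 4-aminopyridine, which eliminates the
    rebound hyperpolarization and the prominent delay-to-fire.
    """
    if p.g_A <= 0:
        raise ValueError("4-AP simulation requires a model with an A-type current")
    baseline = _latency_record(p.with_(sf_gA=1.0), config)
    blocked = _latency_record(p.with_(sf_gA=0.0), config)
    flip = (baseline.get("class") == "type-B" and blocked.get("class") == "type-A")
    return {"baseline": baseline, "blocked": blocked, "classification_flip": flip}


def synaptic_conductance_map(p: ModelParameters,
                             g_synI_values: Sequence[float] = (0.0, 6.0, 12.0, 18.0),
                             g_synE_values: Sequence[float] = (0.0, 3.0, 6.0, 9.0),
                             sf_gA_values: Sequence[float] = (0.1, 0.9),
                             drive: Optional[SynapticDrive] = None,
                             duration_ms: float = 10_000.0,
                             discard_ms: float = 2_000.0,
                             seed: int = 0) -> SweepResult:
    """Firing-rate heatmap under inhibitory/excitatory GABAergic drive.

    One shared drive waveform s(t) is applied at every grid point (so the
    map is comparable across points and reproducible given the seed).
    Inhibitory and excitatory conductances are swept separately (one of the
    two is nonzero at a time, as in the source heatmaps).
    """
    if drive is None:
        from .synth import generate_synaptic_gating
        # dense, brief events: individual conductance transients stay small
        # relative to the cell's excitable range, so excitation excites
        # rather than driving depolarization block
        drive = generate_synaptic_gating(80.0, 2.0, duration_ms, seed=seed)
    records = []
    grid = []
    proto = StimulusProtocol.constant(0.0, duration_ms, name="synmap")
    for sf_g in sf_gA_values:
        combos = [("I", g) for g in g_synI_values] + [("E", g) for g in g_synE_values if g > 0]
        for polarity, g in combos:
            q = p.with_(sf_gA=float(sf_g),
                        g_synI=float(g) if polarity == "I" else 0.0,
                        g_synE=float(g) if polarity == "E" else 0.0)
            rec: dict = {"sf_gA": float(sf_g), "polarity": polarity,
                         "g_syn_nS": float(g)}
            try:
                rb = find_resting_behavior(q, 0.0, options=_FAST)
                init = rb.state if rb.mode == "fixed-point" else rb.cycle.meta["final_state"]
                tr = integrate(q, proto, init, _FAST,
                               drive_E=drive if polarity == "E" else None,
                               drive_I=drive if polarity == "I" else None)
                sp = detect_spikes(tr.window(discard_ms, duration_ms))
                rec["rate_hz"] = sp.count / ((duration_ms - discard_ms) / 1000.0)
                rec["ok"] = True
            except Exception as err:
                rec["ok"] = False
                rec["error"] = str(err)
            records.append(rec)
            grid.append((float(sf_g), polarity, float(g)))
    return SweepResult(("sf_gA", "polarity", "g_syn_nS"), grid, records,
                       provenance={"seed": seed, "drive_rate_note": "shared across grid"})


def spiking_onset_scan(p: ModelParameters, control: str,
                       grid: Sequence[float],
                       settle_ms: float = 8_000.0,
                       continuous_mV: float = 1.0,
                       abrupt_mV: float = 10.0) -> dict:
    """Classify the onset of spiking along a control-parameter sweep.

    ``control`` is "I_app" or "sf_leak".  The scan runs the grid upward and
    downward, recording oscillation amplitude at each point (0 for a fixed
    point).  Amplitude growing continuously from < ``continuous_mV`` at the
    first oscillating point implies a supercritical-like onset; a first
    amplitude >= ``abrupt_mV`` or hysteresis between sweep directions
    implies a subcritical-like onset.  Simulation-based only -- no
    continuation machinery.
    """
    if control not in ("I_app", "sf_leak"):
        raise ValueError("control must be 'I_app' or 'sf_leak'")

    def amplitude(value: float, init=None):
        if control == "I_app":
            q, I = p, float(value)
        else:
            q, I = p.with_(sf_leak=float(value)), 0.0
        try:
            rb = find_resting_behavior(q, I, settle_ms=settle_ms,
                                       analysis_ms=min(4000.0, settle_ms / 2),
                                       options=_FAST, init=init)
        except Exception:
            return np.nan, None
        if rb.mode == "fixed-point":
            return 0.0, rb.state
        return float(rb.v_max - rb.v_min), rb.cycle.meta["final_state"]

    up, down = [], []
    state = None
    for v in grid:
        a, state = amplitude(v, state)
        up.append(a)
    state = None
    for v in reversed(grid):
        a, state = amplitude(v, state)
        down.append(a)
    down = down[::-1]
    up_arr, down_arr = np.array(up), np.array(down)

    osc_up = np.flatnonzero(up_arr > 1e-3)
    if osc_up.size == 0 or osc_up.size == len(grid):
        return {"transition_found": False, "grid": list(grid),
                "amplitude_up": up, "amplitude_down": down}
    first_amp = up_arr[osc_up[0]]
    hysteresis = bool(np.any(np.abs(up_arr - down_arr) > abrupt_mV / 2))
    if first_amp < continuous_mV and not hysteresis:
        onset = "supercritical-like"
    elif first_amp >= abrupt_mV or hysteresis:
        onset = "subcritical-like"
    else:
        onset = "indeterminate"
    return {"transition_found": True, "onset": onset,
            "first_oscillation_amplitude_mV": float(first_amp),
            "hysteresis": hysteresis, "grid": list(grid),
            "amplitude_up": up, "amplitude_down": down}
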