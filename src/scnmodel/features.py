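"""Passive-property measurement and evoked-response classification.

Implements the standard current-clamp characterization of SCN neurons:
resting membrane potential (RMP) and spontaneous firing rate (SFR) over a
30 s window, input resistance by Ohm's law from a -30 pA / 500 ms pulse,
adaptation classes for depolarizing pulses (non-adapting, adapting-firing,
adapting-to-silent), Type-A versus Type-B responses to hyperpolarizing
pulses (rebound spike versus rebound hyperpolarization with delay-to-fire),
and the spontaneous electrical-state taxonomy (depolarized-silent, DLAMO,
firing, hyperpolarized-silent).

All classifiers are deterministic, threshold-configurable, and report the
evidence values they used, so any decision is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .simulation import SimulatedTrace, SpikeCriteria, SpikeTrain, detect_spikes

__all__ = [
    "FeatureConfig",
    "PassiveProperties",
    "EvokedClassification",
    "measure_rmp_sfr",
    "measure_input_resistance",
    "classify_depolarizing_response",
    "measure_delay_to_fire",
    "classify_electrical_state",
    "spike_peaks",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds for the classifiers; defaults are declared package choices.

    ``typeB_latency_ms`` sits between the shortest delay-to-fire reported in
    delay cells (160 ms) and the latency after pharmacological A-current
    blockade (~86 ms), so it separates the two populations.
    """

    spike: SpikeCriteria = SpikeCriteria()
    # depolarizing-pulse adaptation
    nonadapting_rate_ratio: float = 0.75
    amplitude_decline_frac: float = 0.20
    silent_tail_ms: float = 500.0
    # hyperpolarizing-pulse delay classification
    typeB_latency_ms: float = 150.0
    post_spike_search_ms: float = 5_000.0
    # electrical state
    firing_sfr_hz: float = 0.1
    dlamo_vpp_min_mV: float = 2.0
    dlamo_vpp_max_mV: float = 15.0
    depolarized_mean_mV: float = -40.0
    # spike masking for mean-voltage measurements
    spike_mask_ms: float = 8.0


@dataclass(frozen=True)
class PassiveProperties:
    RMP_mV: float
    SFR_Hz: float
    R_input_GOhm: Optional[float] = None
    windows_ms: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class EvokedClassification:
    depolarizing_class: Optional[str] = None   # non-adapting | adapting-firing | adapting-to-silent
    hyperpolarizing_class: Optional[str] = None  # type-A | type-B
    delay_latency_ms: Optional[float] = None
    rebound_spike: Optional[bool] = None
    sag_amplitude_mV: Optional[float] = None
    dlamo: Optional[bool] = None
    electrical_state: Optional[str] = None
    evidence: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def _mask_spikes(trace: SimulatedTrace, spikes: SpikeTrain, pad_ms: float) -> np.ndarray:
    """Boolean mask of samples at least pad_ms away from any spike."""
    keep = np.ones(trace.t_ms.size, dtype=bool)
    for ts in spikes.times_ms:
        keep &= ~((trace.t_ms >= ts - pad_ms) & (trace.t_ms <= ts + pad_ms))
    return keep


def measure_rmp_sfr(trace: SimulatedTrace, window_ms: float = 30_000.0,
                    config: FeatureConfig = FeatureConfig(),
                    mask_spikes: bool = False) -> tuple[float, float]:
    """RMP (mean voltage) and SFR (spikes per second) over a terminal window.

    The default RMP includes spikes, matching the standard mean-voltage
    procedure; ``mask_spikes=True`` gives a spike-masked alternative.
    The trace must be at constant applied current over the window.
    """
    if window_ms > trace.duration_ms + 1e-9:
        raise ValueError(f"window {window_ms} ms exceeds trace span {trace.duration_ms} ms")
    w = trace.window(trace.t_ms[-1] - window_ms, trace.t_ms[-1])
    if np.ptp(w.I_app_pA) > 1e-9:
        raise ValueError("applied current is not constant over the RMP/SFR window")
    spikes = detect_spikes(w, config.spike)
    sfr = spikes.count / (window_ms / 1000.0)
    if mask_spikes and spikes.count:
        keep = _mask_spikes(w, spikes, config.spike_mask_ms)
        rmp = float(w.V_mV[keep].mean()) if keep.any() else float(w.V_mV.mean())
    else:
        rmp = float(w.V_mV.mean())
    return rmp, sfr


def _pulse_bounds(trace: SimulatedTrace) -> tuple[float, float, float]:
    """(onset, offset, amplitude) of the single annotated pulse segment."""
    if trace.protocol is None or not trace.protocol.segments:
        raise ValueError("trace has no annotated pulse segment")
    if len(trace.protocol.segments) != 1:
        raise ValueError("expected exactly one pulse segment in the protocol")
    onset, dur, amp = trace.protocol.segments[0]
    return onset, onset + dur, amp


def measure_input_resistance(trace: SimulatedTrace,
                             config: FeatureConfig = FeatureConfig(),
                             steady_ms: float = 100.0) -> PassiveProperties:
    """Input resistance by Ohm's law from a hyperpolarizing pulse.

    R = dV/dI with dV = (mean V over the last ``steady_ms`` of the pulse)
    minus (mean V over ``steady_ms`` before the pulse); spikes are masked
    from both windows.  A spike inside the pulse tail flags the estimate
    unreliable.
    """
    onset, offset, amp = _pulse_bounds(trace)
    if amp >= 0:
        raise ValueError("input-resistance pulse must be hyperpolarizing")
    spikes = detect_spikes(trace, config.spike)
    keep = _mask_spikes(trace, spikes, config.spike_mask_ms)
    pre = (trace.t_ms >= onset - steady_ms) & (trace.t_ms < onset)
    tail = (trace.t_ms >= offset - steady_ms) & (trace.t_ms < offset)
    flags = []
    if not (keep & tail).any():
        flags.append("unreliable: spiking throughout pulse tail")
        tail_keep = tail
    else:
        tail_keep = keep & tail
        if np.any(~keep & tail):
            flags.append("unreliable: spikes in pulse tail")
    pre_keep = (keep & pre) if (keep & pre).any() else pre
    dV = float(trace.V_mV[tail_keep].mean() - trace.V_mV[pre_keep].mean())
    R = dV / amp  # mV / pA = GOhm
    rmp = float(trace.V_mV[pre_keep].mean())
    sfr = spikes.rate_hz(trace.t_ms[0], onset) if onset > 0 else 0.0
    return PassiveProperties(rmp, sfr, R,
                             windows_ms={"pre": (onset - steady_ms, onset),
                                         "tail": (offset - steady_ms, offset)},
                             flags=tuple(flags))


def spike_peaks(trace: SimulatedTrace, spikes: SpikeTrain,
                search_ms: float = 5.0) -> np.ndarray:
    """Peak voltage of each detected spike (max V within search_ms after threshold)."""
    peaks = np.empty(spikes.count)
    for i, ts in enumerate(spikes.times_ms):
        m = (trace.t_ms >= ts) & (trace.t_ms <= ts + search_ms)
        peaks[i] = trace.V_mV[m].max() if m.any() else np.nan
    return peaks


def classify_depolarizing_response(trace: SimulatedTrace,
                                   config: FeatureConfig = FeatureConfig()) -> EvokedClassification:
    """Adaptation class of the response to a depolarizing pulse.

    adapting-to-silent iff no spikes in the final ``silent_tail_ms`` of the
    pulse; otherwise non-adapting iff the second-half/first-half rate ratio
    is >= ``nonadapting_rate_ratio`` AND the spike-amplitude decline stays
    under ``amplitude_decline_frac``; otherwise adapting-firing.
    """
    onset, offset, amp = _pulse_bounds(trace)
    if amp <= 0:
        raise ValueError("depolarizing classification requires a positive pulse")
    spikes = detect_spikes(trace, config.spike)
    in_pulse = spikes.times_ms[(spikes.times_ms >= onset) & (spikes.times_ms < offset)]
    if in_pulse.size == 0:
        return EvokedClassification(flags=("unclassifiable: no spikes during pulse",))
    mid = 0.5 * (onset + offset)
    n1 = int((in_pulse < mid).sum())
    n2 = int((in_pulse >= mid).sum())
    rate_ratio = n2 / n1 if n1 else np.inf
    tail_silent = not np.any(in_pulse >= offset - config.silent_tail_ms)

    w = trace.window(onset, offset)
    in_spikes = detect_spikes(w, config.spike)
    pk = spike_peaks(w, in_spikes)
    baseline = w.V_mV.min()
    amps = pk - baseline
    # robust decline: typical first-half amplitude vs the final spikes
    first_half = amps[in_spikes.times_ms < mid]
    tail_amps = amps[-min(3, amps.size):]
    if first_half.size and np.median(first_half) > 0:
        decline = float(1.0 - np.median(tail_amps) / np.median(first_half))
    else:
        decline = 0.0

    if tail_silent:
        cls = "adapting-to-silent"
    elif rate_ratio >= config.nonadapting_rate_ratio and decline < config.amplitude_decline_frac:
        cls = "non-adapting"
    else:
        cls = "adapting-firing"
    return EvokedClassification(
        depolarizing_class=cls,
        evidence={"rate_ratio": rate_ratio, "amplitude_decline": decline,
                  "n_first_half": n1, "n_second_half": n2,
                  "tail_silent": tail_silent})


def measure_delay_to_fire(trace: SimulatedTrace,
                          config: FeatureConfig = FeatureConfig()) -> EvokedClassification:
    """Latency to fire after a hyperpolarizing pulse, Type-A/B class, sag.

    Latency runs from pulse offset to the first spike.  Type-B requires
    latency above ``typeB_latency_ms`` AND a post-offset dip below the
    pre-pulse RMP (the rebound hyperpolarization); otherwise Type-A.  Sag is
    (most negative V in the first 200 ms of the pulse) minus (mean V over
    the last 100 ms of the pulse), reported positive when a depolarizing
    sag exists.
    """
    onset, offset, amp = _pulse_bounds(trace)
    if amp >= 0:
        raise ValueError("delay-to-fire requires a hyperpolarizing pulse")
    spikes = detect_spikes(trace, config.spike)
    pre_spikes = spikes.times_ms[spikes.times_ms < onset]
    flags = []
    if pre_spikes.size == 0:
        flags.append("cell not spiking before pulse")

    m_early = (trace.t_ms >= onset) & (trace.t_ms < onset + 200.0)
    m_late = (trace.t_ms >= offset - 100.0) & (trace.t_ms < offset)
    sag = float(trace.V_mV[m_late].mean() - trace.V_mV[m_early].min())
    sag = max(sag, 0.0)

    post = spikes.times_ms[spikes.times_ms >= offset]
    if post.size == 0 or post[0] - offset > config.post_spike_search_ms:
        return EvokedClassification(sag_amplitude_mV=sag,
                                    flags=tuple(flags) + ("latency undefined: no post-pulse spike",))
    latency = float(post[0] - offset)

    keep = _mask_spikes(trace, spikes, config.spike_mask_ms)
    pre_m = (trace.t_ms >= onset - 500.0) & (trace.t_ms < onset) & keep
    pre_rmp = float(trace.V_mV[pre_m].mean()) if pre_m.any() else float(trace.V_mV[trace.t_ms < onset].mean())
    post_m = (trace.t_ms >= offset + 2.0) & (trace.t_ms < post[0] - 1.0)
    post_min = float(trace.V_mV[post_m].min()) if post_m.any() else np.inf
    rebound_hyp = post_min < pre_rmp

    if latency > config.typeB_latency_ms and rebound_hyp:
        cls = "type-B"
    else:
        cls = "type-A"
    return EvokedClassification(
        hyperpolarizing_class=cls,
        delay_latency_ms=latency,
        rebound_spike=(cls == "type-A" and latency < config.typeB_latency_ms),
        sag_amplitude_mV=sag,
        evidence={"pre_rmp": pre_rmp, "post_offset_min": post_min,
                  "rebound_hyperpolarization": rebound_hyp},
        flags=tuple(flags))


def classify_electrical_state(trace: SimulatedTrace,
                              config: FeatureConfig = FeatureConfig()) -> EvokedClassification:
    """Spontaneous electrical state of a >= 10 s zero-current trace.

    firing if SFR > 0.1 Hz; else DLAMO if spikeless with 2-15 mV
    peak-to-peak oscillation at a depolarized mean; else depolarized-silent
    or hyperpolarized-silent by the mean-voltage threshold.
    """
    if trace.duration_ms < 10_000.0 - 1e-6:
        raise ValueError("electrical-state classification needs >= 10 s of trace")
    spikes = detect_spikes(trace, config.spike)
    sfr = spikes.count / (trace.duration_ms / 1000.0)
    vpp = float(np.ptp(trace.V_mV))
    vmean = float(trace.V_mV.mean())
    if sfr > config.firing_sfr_hz:
        state = "firing"
        dlamo = False
    elif (config.dlamo_vpp_min_mV <= vpp <= config.dlamo_vpp_max_mV
          and vmean > config.depolarized_mean_mV):
        state = "DLAMO"
        dlamo = True
    elif vmean > config.depolarized_mean_mV:
        state = "depolarized-silent"
        dlamo = False
    else:
        state = "hyperpolarized-silent"
        dlamo = False
    return EvokedClassification(
        electrical_state=state, dlamo=dlamo,
        evidence={"SFR_Hz": sfr, "Vpp_mV": vpp, "Vmean_mV": vmean})
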