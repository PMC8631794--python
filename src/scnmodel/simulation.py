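"""Numerical integration of the SCN neuron model and basic trace analysis.

Integrates the stiff model ODEs under piecewise-constant current-injection
protocols (restarting the solver at every segment boundary so discontinuous
I_app is handled exactly), locates resting behavior (fixed point versus
spontaneous oscillation), detects spikes, and measures f-I curves.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import (
    ModelParameters,
    ModelState,
    SynapticDrive,
    array_to_state,
    make_fast_rhs,
    membrane_currents,
    state_to_array,
    steady_gates_at,
    DYNAMIC_GATES,
)

__all__ = [
    "StimulusProtocol",
    "SimulatedTrace",
    "SpikeTrain",
    "SolverOptions",
    "SpikeCriteria",
    "RestingBehavior",
    "IntegrationError",
    "integrate",
    "find_resting_behavior",
    "detect_spikes",
    "fI_curve",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time the state was still valid."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(f"{message} (last valid t = {last_valid_time:.3f} ms)")
        self.last_valid_time = last_valid_time


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant current injection: baseline plus step segments.

    Each segment (onset_ms, duration_ms, amplitude_pA) adds its amplitude to
    the baseline over [onset, onset + duration).  Segments must not overlap
    and must fall inside the total duration.
    """

    name: str
    baseline_pA: float
    segments: tuple[tuple[float, float, float], ...]
    total_duration_ms: float

    def __post_init__(self) -> None:
        segs = sorted(self.segments)
        for onset, dur, _amp in segs:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if onset < 0 or onset + dur > self.total_duration_ms + 1e-9:
                raise ValueError("segment outside protocol duration")
        for (o1, d1, _), (o2, _, _) in zip(segs, segs[1:]):
            if o2 < o1 + d1 - 1e-9:
                raise ValueError("segments overlap")

    def current_at(self, t: float) -> float:
        I = self.baseline_pA
        for onset, dur, amp in self.segments:
            if onset <= t < onset + dur:
                I += amp
        return I

    def breakpoints(self) -> np.ndarray:
        """Times at which I_app jumps, plus the endpoints."""
        pts = {0.0, self.total_duration_ms}
        for onset, dur, _ in self.segments:
            pts.add(onset)
            pts.add(min(onset + dur, self.total_duration_ms))
        return np.array(sorted(pts))

    def current_samples(self, t: np.ndarray) -> np.ndarray:
        I = np.full(t.shape, self.baseline_pA)
        for onset, dur, amp in self.segments:
            I[(t >= onset) & (t < onset + dur)] += amp
        return I

    @staticmethod
    def constant(I_pA: float, duration_ms: float, name: str = "hold") -> "StimulusProtocol":
        return StimulusProtocol(name, I_pA, (), duration_ms)

    @staticmethod
    def single_pulse(amplitude_pA: float, onset_ms: float, duration_ms: float,
                     total_ms: float, baseline_pA: float = 0.0,
                     name: Optional[str] = None) -> "StimulusProtocol":
        name = name or f"pulse_{amplitude_pA:+g}pA"
        return StimulusProtocol(name, baseline_pA,
                                ((onset_ms, duration_ms, amplitude_pA),), total_ms)


@dataclass
class SimulatedTrace:
    """Uniformly sampled (t, V, I_app) with optional gating/current channels."""

    t_ms: np.ndarray
    V_mV: np.ndarray
    I_app_pA: np.ndarray
    gates: Optional[dict[str, np.ndarray]] = None
    currents: Optional[dict[str, np.ndarray]] = None
    meta: dict = field(default_factory=dict)
    protocol: Optional[StimulusProtocol] = None

    def __post_init__(self) -> None:
        n = self.t_ms.size
        if self.V_mV.size != n or self.I_app_pA.size != n:
            raise ValueError("t, V, I_app must have equal length")
        dt = np.diff(self.t_ms)
        if n > 1 and (np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0]) if self.t_ms.size > 1 else 0.0

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    def window(self, t0: float, t1: float) -> "SimulatedTrace":
        """Sub-trace over [t0, t1]."""
        m = (self.t_ms >= t0 - 1e-9) & (self.t_ms <= t1 + 1e-9)
        return SimulatedTrace(
            self.t_ms[m], self.V_mV[m], self.I_app_pA[m],
            {k: v[m] for k, v in self.gates.items()} if self.gates else None,
            {k: v[m] for k, v in self.currents.items()} if self.currents else None,
            dict(self.meta), self.protocol)

    def dVdt(self, p: ModelParameters) -> np.ndarray:
        """dV/dt along the trace from the model equations (for phase plots).

        Requires stored gating trajectories; uses the rhs, not finite
        differences.
        """
        if not self.gates:
            raise ValueError("gating trajectories were not stored")
        f = make_fast_rhs(p)
        out = np.empty(self.t_ms.size)
        for i, t in enumerate(self.t_ms):
            y = (self.V_mV[i],) + tuple(self.gates[g][i] for g in DYNAMIC_GATES)
            out[i] = f(t, y, self.I_app_pA[i])[0]
        return out


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike times plus the criteria that produced them."""

    times_ms: np.ndarray
    threshold_mV: float
    refractory_ms: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.times_ms.size)

    def rate_hz(self, t0_ms: float, t1_ms: float) -> float:
        n = int(np.sum((self.times_ms >= t0_ms) & (self.times_ms < t1_ms)))
        return n / ((t1_ms - t0_ms) / 1000.0)


@dataclass(frozen=True)
class SolverOptions:
    """Integration settings: stiff adaptive solver, tight default tolerances."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dt_ms: float = 0.04  # 25 kHz, matching the recording sample rate
    max_step_ms: float = np.inf


@dataclass(frozen=True)
class SpikeCriteria:
    """Upward threshold crossing with refractory enforcement.

    SCN action potentials are small; the default -20 mV crossing with a 2 ms
    refractory is robust for both model and noisy synthetic traces.
    """

    threshold_mV: float = -20.0
    refractory_ms: float = 2.0


def _params_hash(p: ModelParameters) -> str:
    return hashlib.sha1(repr(p).encode()).hexdigest()[:12]


def integrate(p: ModelParameters, proto: StimulusProtocol, init: ModelState,
              options: SolverOptions = SolverOptions(),
              drive_E: Optional[SynapticDrive] = None,
              drive_I: Optional[SynapticDrive] = None,
              store_gates: bool = False,
              store_currents: bool = False) -> SimulatedTrace:
    """Integrate the model under a protocol; returns a uniformly sampled trace.

    The solver restarts at every protocol breakpoint so the discontinuous
    applied current is handled exactly.  Deterministic: identical inputs give
    identical outputs.
    """
    f = make_fast_rhs(p, drive_E, drive_I)
    dt = options.output_dt_ms
    n_out = int(round(proto.total_duration_ms / dt)) + 1
    t_out = np.arange(n_out) * dt
    V = np.empty(n_out)
    gate_tracks = np.empty((6, n_out)) if (store_gates or store_currents) else None

    y = state_to_array(init)
    bps = proto.breakpoints()
    for a, b in zip(bps[:-1], bps[1:]):
        I_app = proto.current_at(0.5 * (a + b))
        idx = np.nonzero((t_out >= a - 1e-9) & (t_out <= b + 1e-9))[0]
        t_eval = list(t_out[idx])
        # always evaluate the segment end so the restart state is exact
        extra_end = not t_eval or t_eval[-1] < b - 1e-12
        if extra_end:
            t_eval.append(b)
        sol = solve_ivp(lambda t, yy: f(t, yy, I_app), (a, b), y,
                        method=options.method, rtol=options.rtol,
                        atol=options.atol, t_eval=t_eval,
                        max_step=options.max_step_ms, dense_output=False)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"solver failed: {sol.message}", float(a))
        y = sol.y[:, -1]
        ys = sol.y[:, :-1] if extra_end else sol.y
        V[idx] = ys[0]
        if gate_tracks is not None:
            gate_tracks[:, idx] = ys[1:]

    I_arr = proto.current_samples(t_out)
    gates = None
    currents = None
    if gate_tracks is not None:
        gates = {name: np.clip(gate_tracks[i], 0.0, 1.0)
                 for i, name in enumerate(DYNAMIC_GATES)}
        if store_currents:
            currents = _channel_currents(t_out, V, gates, p, drive_E, drive_I)
        if not store_gates:
            gates = None
    meta = {"params_hash": _params_hash(p), "solver": options.method,
            "rtol": options.rtol, "atol": options.atol,
            "final_state": array_to_state(y)}
    return SimulatedTrace(t_out, V, I_arr, gates, currents, meta, proto)


def _channel_currents(t, V, gates, p, drive_E, drive_I):
    names = ("I_Na", "I_K", "I_Ca", "I_LNa", "I_LK", "I_H", "I_A",
             "I_synE", "I_synI", "G_Na", "G_K", "G_Ca", "G_H", "G_A")
    out = {n: np.empty(t.size) for n in names}
    for i in range(t.size):
        st = ModelState(V[i], *(gates[g][i] for g in DYNAMIC_GATES))
        sE = drive_E(t[i]) if drive_E is not None else 0.0
        sI = drive_I(t[i]) if drive_I is not None else 0.0
        cb = membrane_currents(st, p, sE, sI)
        for n in names:
            out[n][i] = getattr(cb, n)
    return out


def detect_spikes(trace: SimulatedTrace,
                  criteria: SpikeCriteria = SpikeCriteria()) -> SpikeTrain:
    """One spike per upward crossing of the threshold, with refractory.

    Crossing times are linearly interpolated between samples, so counts are
    invariant to sampling rate for adequately sampled model traces.
    """
    V = trace.V_mV
    t = trace.t_ms
    th = criteria.threshold_mV
    above = V >= th
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    times = []
    last = -np.inf
    for i in idx:
        # linear interpolation of the crossing time
        tc = t[i] + (th - V[i]) / (V[i + 1] - V[i]) * (t[i + 1] - t[i])
        if tc - last >= criteria.refractory_ms:
            times.append(tc)
            last = tc
    return SpikeTrain(np.asarray(times), th, criteria.refractory_ms)


@dataclass(frozen=True)
class RestingBehavior:
    """Classification of the model's long-run behavior at constant current."""

    mode: str  # "fixed-point" | "oscillating"
    state: Optional[ModelState] = None          # polished fixed point
    rate_hz: float = 0.0                        # spike rate when oscillating
    period_ms: Optional[float] = None
    v_min: Optional[float] = None
    v_max: Optional[float] = None
    cycle: Optional[SimulatedTrace] = None      # one-cycle sample


class UndeterminedModeError(RuntimeError):
    pass


def find_resting_behavior(p: ModelParameters, I_app: float = 0.0,
                          settle_ms: float = 10_000.0,
                          analysis_ms: float = 4_000.0,
                          options: SolverOptions = SolverOptions(),
                          init: Optional[ModelState] = None) -> RestingBehavior:
    """Settle the model at constant current and classify rest vs oscillation.

    Integrates for ``settle_ms``, inspects the terminal ``analysis_ms``
    window (< 0.5 mV peak-to-peak implies a fixed point, then polished by
    root-finding on the rhs); otherwise reports the oscillation's spike rate,
    period and voltage range with a one-cycle sample.
    """
    if init is None:
        gtot = p.g_LNa_eff + p.g_LK_eff
        V0 = (p.g_LNa_eff * p.E_Na + p.g_LK_eff * p.E_K) / gtot if gtot > 0 else -60.0
        V0 = float(np.clip(V0, -80.0, -30.0))
        init = steady_gates_at(V0, p)
    analysis_ms = min(analysis_ms, 0.5 * settle_ms)  # never include the transient
    opts = SolverOptions(options.method, options.rtol, options.atol,
                         output_dt_ms=0.1, max_step_ms=options.max_step_ms)
    proto = StimulusProtocol.constant(I_app, settle_ms, name="settle")
    trace = integrate(p, proto, init, opts)
    tail = trace.window(settle_ms - analysis_ms, settle_ms)
    vpp = float(np.ptp(tail.V_mV))
    final: ModelState = trace.meta["final_state"]

    if vpp < 0.5:
        f = make_fast_rhs(p)
        sol = root(lambda y: np.asarray(f(0.0, y, I_app)), state_to_array(final),
                   tol=1e-12)
        resid = np.linalg.norm(np.asarray(f(0.0, sol.x, I_app)))
        # accept on residual: root's step-size criterion can report failure
        # at an already-converged point
        if resid > 1e-6:
            raise UndeterminedModeError(
                f"no convergence to a fixed point (|rhs| = {resid:.2e})")
        return RestingBehavior("fixed-point", state=array_to_state(sol.x))

    spikes = detect_spikes(tail)
    rate = spikes.count / (analysis_ms / 1000.0)
    if spikes.count >= 2:
        period = float(np.median(np.diff(spikes.times_ms)))
    else:
        # subthreshold oscillation: period from mean-crossing intervals
        v = tail.V_mV - tail.V_mV.mean()
        up = np.nonzero((v[:-1] < 0) & (v[1:] >= 0))[0]
        if up.size < 2:
            raise UndeterminedModeError("oscillation with undetectable period")
        period = float(np.mean(np.diff(tail.t_ms[up])))
    t1 = tail.t_ms[-1]
    cycle = trace.window(t1 - period, t1)
    return RestingBehavior("oscillating", rate_hz=rate, period_ms=period,
                           v_min=float(tail.V_mV.min()),
                           v_max=float(tail.V_mV.max()), cycle=cycle)


def fI_curve(p: ModelParameters, amplitudes: Sequence[float],
             discard_ms: float = 2_000.0, window_ms: float = 5_000.0,
             options: Optional[SolverOptions] = None,
             init: Optional[ModelState] = None) -> list[dict]:
    """Steady firing rate versus applied current.

    For each amplitude the model is held at that constant current; the first
    ``discard_ms`` are discarded (adaptation transients are much faster than
    2 s in all bundled cells) and the rate is counted over ``window_ms``.
    Per-amplitude failures are flagged, not fatal.
    """
    opts = options or SolverOptions(output_dt_ms=0.1)
    if init is None:
        rb = find_resting_behavior(p, 0.0)
        init = rb.state if rb.mode == "fixed-point" else _cycle_start(rb)
    out = []
    for I in amplitudes:
        rec: dict = {"I_app_pA": float(I)}
        try:
            proto = StimulusProtocol.constant(I, discard_ms + window_ms)
            tr = integrate(p, proto, init, opts)
            sp = detect_spikes(tr.window(discard_ms, discard_ms + window_ms))
            rec["rate_hz"] = sp.count / (window_ms / 1000.0)
            rec["ok"] = True
        except IntegrationError as err:
            rec["rate_hz"] = float("nan")
            rec["ok"] = False
            rec["error"] = str(err)
        out.append(rec)
    return out


def _cycle_start(rb: RestingBehavior) -> ModelState:
    assert rb.cycle is not None
    meta_state = rb.cycle.meta.get("final_state")
    return meta_state
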