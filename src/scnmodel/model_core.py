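"""Conductance-based model of SCN neurons: types, gating functions, currents, ODE right-hand side.

The model is a single-compartment Hodgkin-Huxley-type description of a
suprachiasmatic nucleus (SCN) neuron with transient sodium (I_Na), delayed
rectifier potassium (I_K), transient calcium (I_Ca), separate sodium and
potassium leaks (I_LNa, I_LK), and two optional currents used for cells with
delay-to-fire responses: a hyperpolarization-activated cation current (I_H)
and a transient subthreshold A-type potassium current (I_A).  Inhibitory and
excitatory GABAergic synaptic currents gate on an externally supplied
waveform s(t).

Units are canonical throughout the package: mV, ms, pA, nS, pF.  These are
self-consistent (pF*mV/ms = pA = nS*mV), so no hidden conversions occur.

Membrane equation::

    C dV/dt = I_app(t) - I_Na - I_K - I_Ca - I_LNa - I_LK - I_H - I_A
              - I_synE - I_synI

with, e.g., I_Na = g_Na * mNa_inf(V)^3 * hNa * (V - E_Na) and
I_A = sf_gA * g_A * mA_inf(V)^3 * hA * (V - E_K).  Each gating variable q
relaxes as dq/dt = (q_inf(V) - q) / tau_q(V) with

    q_inf(V)  = 1/2 + 1/2 * tanh((V - v_half) / dv)
    tau_q(V)  = tau0 + tau1 * (1 - tanh^2((V - v_half) / dv))

Inactivation gates use a negative ``dv`` (decreasing sigmoid).  Sodium and
A-type activations (mNa, mA) are instantaneous: evaluated as q_inf(V) at
every right-hand-side call rather than carried as state.

Three dimensionless scaling factors support the mechanism experiments:
``sf_gA`` multiplies g_A, ``sf_tau_hA`` multiplies tau_hA(V), and
``sf_leak`` divides g_LNa while multiplying g_LK (the circadian "bicycle"
knob: < 1 is a daytime up-state, > 1 a night-time down-state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "GateKinetics",
    "ModelParameters",
    "ModelState",
    "SynapticDrive",
    "CurrentBreakdown",
    "GATE_NAMES",
    "ACTIVATION_EXPONENTS",
    "gate_steady_state",
    "gate_time_constant",
    "membrane_currents",
    "rhs",
    "state_to_array",
    "array_to_state",
    "steady_gates_at",
]

#: Gate names in canonical order.  mNa and mA are instantaneous (not state).
GATE_NAMES = ("mNa", "hNa", "n", "mCa", "hCa", "mH", "mA", "hA")

#: Names of the gates carried as dynamic state, in state-vector order
#: (the state vector is [V, hNa, n, mCa, hCa, mH, hA]).
DYNAMIC_GATES = ("hNa", "n", "mCa", "hCa", "mH", "hA")

#: Activation-exponent table.  These are data so tests can assert them,
#: not literals buried in the rhs: I_Na ~ mNa^3 hNa, I_K ~ n^4,
#: I_Ca ~ mCa hCa, I_H ~ mH, I_A ~ mA^3 hA.
ACTIVATION_EXPONENTS = {
    "mNa": 3,
    "hNa": 1,
    "n": 4,
    "mCa": 1,
    "hCa": 1,
    "mH": 1,
    "mA": 3,
    "hA": 1,
}


class DomainError(ValueError):
    """Raised when an input falls outside an operation's domain (e.g. non-finite voltage)."""


class ContractError(ValueError):
    """Raised when an operation is called outside its contract (e.g. tau of an instantaneous gate)."""


@dataclass(frozen=True)
class GateKinetics:
    """Voltage-dependent kinetics of one gating variable.

    ``v_half`` (mV) and ``dv`` (mV, signed) set the steady-state sigmoid;
    a negative ``dv`` yields a decreasing (inactivation-type) sigmoid.
    ``tau0``/``tau1`` (ms) set the time-constant profile
    tau(V) = tau0 + tau1*(1 - tanh^2((V - v)/dv)), which by default shares
    (v_half, dv) with the steady state; ``v_half_tau``/``dv_tau`` optionally
    override the center/width of the tau profile only.  ``instantaneous``
    gates are slaved to their steady state and carry no ODE.
    """

    v_half: float
    dv: float
    tau0: float = 1.0
    tau1: float = 0.0
    instantaneous: bool = False
    v_half_tau: Optional[float] = None
    dv_tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dv == 0:
            raise ValueError("dv must be nonzero")
        if not self.instantaneous:
            if not self.tau0 > 0:
                raise ValueError("tau0 must be > 0 for a dynamic gate")
            if self.tau0 + min(0.0, self.tau1) <= 0:
                raise ValueError("tau(V) must stay positive: tau0 + min(0, tau1) > 0")
        if (self.v_half_tau is None) != (self.dv_tau is None):
            raise ValueError("v_half_tau and dv_tau must be overridden together")


def _default_kinetics() -> dict[str, GateKinetics]:
    # Placeholder kinetics; real cells come from the fixture files.
    return {
        "mNa": GateKinetics(-35.0, 9.0, instantaneous=True),
        "hNa": GateKinetics(-62.0, -14.0, 1.0, 5.0),
        "n": GateKinetics(-30.0, 14.0, 1.0, 4.0),
        "mCa": GateKinetics(-30.0, 11.0, 1.0, 2.0),
        "hCa": GateKinetics(-50.0, -13.0, 60.0, 120.0),
        "mH": GateKinetics(-75.0, -9.0, 200.0, 300.0),
        "mA": GateKinetics(-45.0, 12.0, instantaneous=True),
        "hA": GateKinetics(-70.0, -9.0, 140.0, 50.0),
    }


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set: capacitance, maximal conductances, reversal
    potentials, per-gate kinetics, and the three scaling factors.

    The basic cell (no sag, no delay-to-fire, no synapses) is the special
    case g_H = g_A = g_synE = g_synI = 0.
    """

    C: float = 5.7  # pF
    g_Na: float = 100.0  # nS
    g_K: float = 10.0
    g_Ca: float = 10.0
    g_LNa: float = 0.2
    g_LK: float = 0.3
    g_H: float = 0.0
    g_A: float = 0.0
    g_synE: float = 0.0
    g_synI: float = 0.0
    E_Na: float = 45.0  # mV
    E_K: float = -97.0
    E_Ca: float = 54.0
    E_H: float = -35.0
    E_synE: float = 0.0
    E_synI: float = -85.0
    kinetics: dict[str, GateKinetics] = field(default_factory=_default_kinetics)
    sf_gA: float = 1.0
    sf_tau_hA: float = 1.0
    sf_leak: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K", "g_Ca", "g_LNa", "g_LK", "g_H", "g_A",
                     "g_synE", "g_synI"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.C > 0:
            raise ValueError("C must be > 0")
        if not self.E_Na > self.E_K:
            raise ValueError("E_Na must exceed E_K")
        if self.sf_gA < 0 or not self.sf_tau_hA > 0 or not self.sf_leak > 0:
            raise ValueError("scaling factors out of range")
        missing = set(GATE_NAMES) - set(self.kinetics)
        if missing:
            raise ValueError(f"missing kinetics for gates: {sorted(missing)}")
        if not self.kinetics["mNa"].instantaneous or not self.kinetics["mA"].instantaneous:
            raise ValueError("mNa and mA must be instantaneous gates")

    # -- effective conductances after scaling factors -------------------
    @property
    def g_A_eff(self) -> float:
        return self.sf_gA * self.g_A

    @property
    def g_LNa_eff(self) -> float:
        return self.g_LNa / self.sf_leak

    @property
    def g_LK_eff(self) -> float:
        return self.g_LK * self.sf_leak

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class ModelState:
    """Dynamic state: membrane voltage plus the six non-instantaneous gates."""

    V: float
    hNa: float
    n: float
    mCa: float
    hCa: float
    mH: float = 0.0
    hA: float = 0.0

    def __post_init__(self) -> None:
        for name in DYNAMIC_GATES:
            q = getattr(self, name)
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"gating fraction {name}={q} outside [0, 1]")


@dataclass(frozen=True)
class CurrentBreakdown:
    """Per-channel currents (pA) and active conductances (nS) at one instant.

    Sign convention: currents are written on the right-hand side with a
    minus sign, so an inward (depolarizing) current is negative here
    (e.g. I_Na < 0 below E_Na when the channel is open).
    """

    I_Na: float
    I_K: float
    I_Ca: float
    I_LNa: float
    I_LK: float
    I_H: float
    I_A: float
    I_synE: float
    I_synI: float
    G_Na: float
    G_K: float
    G_Ca: float
    G_H: float
    G_A: float

    @property
    def total(self) -> float:
        """Sum of all membrane currents (pA)."""
        return (self.I_Na + self.I_K + self.I_Ca + self.I_LNa + self.I_LK
                + self.I_H + self.I_A + self.I_synE + self.I_synI)


class SynapticDrive:
    """Sampled synaptic gating waveform s(t) in [0, 1].

    Emulates the gating variable derived from voltage-clamped post-synaptic
    currents; evaluated by hold-previous or linear interpolation.
    """

    def __init__(self, times_ms: np.ndarray, s: np.ndarray,
                 interpolation: str = "previous") -> None:
        times_ms = np.asarray(times_ms, dtype=float)
        s = np.asarray(s, dtype=float)
        if times_ms.ndim != 1 or times_ms.shape != s.shape:
            raise ValueError("times and s must be 1-D arrays of equal length")
        if times_ms.size == 0:
            raise ValueError("drive must have at least one sample")
        if np.any(np.diff(times_ms) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("s(t) must lie in [0, 1]")
        if interpolation not in ("previous", "linear"):
            raise ValueError("interpolation must be 'previous' or 'linear'")
        self.times_ms = times_ms
        self.s = s
        self.interpolation = interpolation

    def __call__(self, t: float | np.ndarray):
        t = np.asarray(t, dtype=float)
        if self.interpolation == "linear":
            out = np.interp(t, self.times_ms, self.s)
        else:
            idx = np.searchsorted(self.times_ms, t, side="right") - 1
            idx = np.clip(idx, 0, self.s.size - 1)
            out = self.s[idx]
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Gating functions
# ---------------------------------------------------------------------------

def gate_steady_state(V, k: GateKinetics):
    """Steady-state open fraction q_inf(V) = 1/2 + 1/2 tanh((V - v_half)/dv).

    Strictly increasing in V for dv > 0 (activation) and strictly decreasing
    for dv < 0 (inactivation); always in (0, 1).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise DomainError("non-finite voltage")
    out = 0.5 + 0.5 * np.tanh((V - k.v_half) / k.dv)
    return float(out) if out.ndim == 0 else out


def gate_time_constant(V, k: GateKinetics, sf: float = 1.0):
    """Relaxation time constant tau(V) = tau0 + tau1*(1 - tanh^2(.)), in ms.

    Symmetric about its center; peaks at tau0 + tau1 there (for tau1 > 0).
    ``sf`` multiplies the whole profile (used for the hA gate's sf_tau_hA).
    """
    if k.instantaneous:
        raise ContractError("instantaneous gate has no time constant")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise DomainError("non-finite voltage")
    vc = k.v_half if k.v_half_tau is None else k.v_half_tau
    dvc = k.dv if k.dv_tau is None else k.dv_tau
    th = np.tanh((V - vc) / dvc)
    out = sf * (k.tau0 + k.tau1 * (1.0 - th * th))
    return float(out) if out.ndim == 0 else out


def steady_gates_at(V: float, p: ModelParameters) -> ModelState:
    """State with every dynamic gate at its steady-state value for voltage V."""
    kin = p.kinetics
    return ModelState(
        V=V,
        hNa=gate_steady_state(V, kin["hNa"]),
        n=gate_steady_state(V, kin["n"]),
        mCa=gate_steady_state(V, kin["mCa"]),
        hCa=gate_steady_state(V, kin["hCa"]),
        mH=gate_steady_state(V, kin["mH"]),
        hA=gate_steady_state(V, kin["hA"]),
    )


# ---------------------------------------------------------------------------
# Currents and right-hand side
# ---------------------------------------------------------------------------

def membrane_currents(state: ModelState, p: ModelParameters,
                      s_E: float = 0.0, s_I: float = 0.0) -> CurrentBreakdown:
    """Evaluate every channel current (pA) and active conductance (nS).

    Instantaneous gates (mNa, mA) are evaluated at the state's voltage.
    Scaling factors are applied here: effective g_A = sf_gA*g_A, effective
    g_LNa = g_LNa/sf_leak, effective g_LK = g_LK*sf_leak.
    """
    if not 0.0 <= s_E <= 1.0 or not 0.0 <= s_I <= 1.0:
        raise DomainError("synaptic gating fractions must lie in [0, 1]")
    V = state.V
    kin = p.kinetics
    e = ACTIVATION_EXPONENTS
    mNa = gate_steady_state(V, kin["mNa"])
    mA = gate_steady_state(V, kin["mA"])

    G_Na = p.g_Na * mNa ** e["mNa"] * state.hNa ** e["hNa"]
    G_K = p.g_K * state.n ** e["n"]
    G_Ca = p.g_Ca * state.mCa ** e["mCa"] * state.hCa ** e["hCa"]
    G_H = p.g_H * state.mH ** e["mH"]
    G_A = p.g_A_eff * mA ** e["mA"] * state.hA ** e["hA"]

    return CurrentBreakdown(
        I_Na=G_Na * (V - p.E_Na),
        I_K=G_K * (V - p.E_K),
        I_Ca=G_Ca * (V - p.E_Ca),
        I_LNa=p.g_LNa_eff * (V - p.E_Na),
        I_LK=p.g_LK_eff * (V - p.E_K),
        I_H=G_H * (V - p.E_H),
        I_A=G_A * (V - p.E_K),
        I_synE=p.g_synE * s_E * (V - p.E_synE),
        I_synI=p.g_synI * s_I * (V - p.E_synI),
        G_Na=G_Na, G_K=G_K, G_Ca=G_Ca, G_H=G_H, G_A=G_A,
    )


def rhs(t: float, state: ModelState, p: ModelParameters, I_app: float = 0.0,
        drive_E: Optional[SynapticDrive] = None,
        drive_I: Optional[SynapticDrive] = None) -> np.ndarray:
    """Time derivative of [V, hNa, n, mCa, hCa, mH, hA].

    dV/dt = (I_app - sum of currents)/C in mV/ms; each dynamic gate relaxes
    toward its steady state.  Absent drives mean s = 0 (the synaptic
    conductance parameters are untouched).
    """
    if not (math.isfinite(t) and math.isfinite(I_app) and math.isfinite(state.V)):
        raise DomainError("non-finite input to rhs")
    s_E = drive_E(t) if drive_E is not None else 0.0
    s_I = drive_I(t) if drive_I is not None else 0.0
    cur = membrane_currents(state, p, s_E, s_I)
    kin = p.kinetics
    V = state.V
    dV = (I_app - cur.total) / p.C
    out = np.empty(7)
    out[0] = dV
    for i, name in enumerate(DYNAMIC_GATES):
        k = kin[name]
        sf = p.sf_tau_hA if name == "hA" else 1.0
        q = getattr(state, name)
        out[i + 1] = (gate_steady_state(V, k) - q) / gate_time_constant(V, k, sf)
    return out


def state_to_array(state: ModelState) -> np.ndarray:
    return np.array([state.V, state.hNa, state.n, state.mCa, state.hCa,
                     state.mH, state.hA])


def array_to_state(y: np.ndarray) -> ModelState:
    q = np.clip(y[1:], 0.0, 1.0)  # guard tiny solver overshoot
    return ModelState(float(y[0]), *map(float, q))


def make_fast_rhs(p: ModelParameters, drive_E: Optional[SynapticDrive] = None,
                  drive_I: Optional[SynapticDrive] = None):
    """Build a closure f(t, y, I_app) -> dy/dt over raw arrays.

    Same dynamics as :func:`rhs` but without dataclass packing, for the
    integrator's inner loop.  Keeping one code path for the science and one
    for speed is avoided by testing their agreement (see the simulation
    tests).
    """
    kin = p.kinetics
    km, kh, kn = kin["mNa"], kin["hNa"], kin["n"]
    kmc, khc, kmh, kha = kin["mCa"], kin["hCa"], kin["mH"], kin["hA"]
    kma = kin["mA"]
    gNa, gK, gCa = p.g_Na, p.g_K, p.g_Ca
    gLNa, gLK = p.g_LNa_eff, p.g_LK_eff
    gH, gA = p.g_H, p.g_A_eff
    gsE, gsI = p.g_synE, p.g_synI
    ENa, EK, ECa, EH = p.E_Na, p.E_K, p.E_Ca, p.E_H
    EsE, EsI = p.E_synE, p.E_synI
    C = p.C
    sf_tau = p.sf_tau_hA
    tanh = math.tanh

    def q_inf(V, k):
        return 0.5 + 0.5 * tanh((V - k.v_half) / k.dv)

    def tau_of(V, k):
        vc = k.v_half if k.v_half_tau is None else k.v_half_tau
        dvc = k.dv if k.dv_tau is None else k.dv_tau
        th = tanh((V - vc) / dvc)
        return k.tau0 + k.tau1 * (1.0 - th * th)

    def f(t, y, I_app):
        V, hNa, n, mCa, hCa, mH, hA = y
        mNa = q_inf(V, km)
        mA = q_inf(V, kma)
        I = (gNa * mNa ** 3 * hNa * (V - ENa)
             + gK * n ** 4 * (V - EK)
             + gCa * mCa * hCa * (V - ECa)
             + gLNa * (V - ENa)
             + gLK * (V - EK)
             + gH * mH * (V - EH)
             + gA * mA ** 3 * hA * (V - EK))
        if gsE and drive_E is not None:
            I += gsE * drive_E(t) * (V - EsE)
        if gsI and drive_I is not None:
            I += gsI * drive_I(t) * (V - EsI)
        return (
            (I_app - I) / C,
            (q_inf(V, kh) - hNa) / tau_of(V, kh),
            (q_inf(V, kn) - n) / tau_of(V, kn),
            (q_inf(V, kmc) - mCa) / tau_of(V, kmc),
            (q_inf(V, khc) - hCa) / tau_of(V, khc),
            (q_inf(V, kmh) - mH) / tau_of(V, kmh),
            (q_inf(V, kha) - hA) / (sf_tau * tau_of(V, kha)),
        )

    return f
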