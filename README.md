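# scnmodel

Conductance-based modelling of suprachiasmatic nucleus (SCN) neurons with
variational parameter estimation from current-clamp recordings.

The SCN is the brain's master circadian clock: its neurons fire faster and
rest more depolarized during the day than at night, and their responses to
synaptic-like current pulses reveal the ionic machinery behind that
rhythm.  `scnmodel` is for electrophysiologists and modellers who want to

- simulate Hodgkin-Huxley-type SCN neuron models (transient Na, delayed
  rectifier K, transient Ca, separate Na/K leaks, optional
  hyperpolarization-activated H and subthreshold A-type K currents, and
  GABAergic synaptic currents of either polarity),
- extract the standard current-clamp features (resting membrane potential,
  spontaneous firing rate, input resistance, adaptation classes,
  Type-A/Type-B hyperpolarization responses, DLAMO/silent/firing states),
- estimate hidden gating states and model parameters directly from
  current-clamp voltage traces by a variational (4D-Var-like) method with
  nudging regularization, multistart, and Pareto model selection, and
- run the mechanism experiments those models enable: circadian leak-ratio
  ("bicycle") sweeps, A-current delay-to-fire latency curves, in-silico
  4-AP blockade, and synaptic-conductance firing-rate maps.

## The model

    C dV/dt = I_app(t) - g_Na mNa_inf(V)^3 hNa (V - E_Na) - g_K n^4 (V - E_K)
              - g_Ca mCa hCa (V - E_Ca) - g_LNa (V - E_Na) - g_LK (V - E_K)
              - g_H mH (V - E_H) - g_A mA_inf(V)^3 hA (V - E_K)
              - g_synE s(t) (V - E_synE) - g_synI s(t) (V - E_synI)

    dq/dt   = (q_inf(V) - q) / tau_q(V),       q in {hNa, n, mCa, hCa, mH, hA}
    q_inf   = 1/2 + 1/2 tanh((V - v_q)/dv_q)
    tau_q   = tau_q0 + tau_q1 (1 - tanh^2((V - v_q)/dv_q))

Sodium and A-type activation are instantaneous.  Three scaling factors
drive the mechanism experiments: `sf_gA` (multiplies g_A), `sf_tau_hA`
(multiplies tau_hA) and `sf_leak` (divides g_LNa, multiplies g_LK; < 1 is
the daytime up-state, > 1 the night down-state).  Units are mV / pA / nS /
pF / ms throughout.  See `docs/methods.md` for the estimation method and
all numerical choices.

## A worked example

```python
from scnmodel import load_fixture, find_resting_behavior
from scnmodel.behavior import simulate_4AP

cell = load_fixture("typeB")          # delay-to-fire cell (synthetic stand-in)
rest = find_resting_behavior(cell, I_app=0.0)
print(rest.mode, round(rest.rate_hz, 1))

out = simulate_4AP(cell)              # zero the A-conductance, as 4-AP does
print(round(out["baseline"]["latency_ms"]), out["baseline"]["class"])
print(round(out["blocked"]["latency_ms"]), out["blocked"]["class"])
```

prints

    oscillating 22.8
    1065 type-B
    13 type-A

With its A-type current intact the cell stays silent for about a second
after a 1 s, -30 pA pulse (the Type-B delay-to-fire response, inside the
published 160-1430 ms range); blocking the A-current converts it to an
immediate rebound spike, the Type-A phenotype.  The scripts in `examples/` walk through each capability the
same way: simulation and passive properties, evoked-response
classification, a twin experiment, the A-current mechanism, and the
circadian leak sweep — each prints the numbers it computes and one line on
what they mean.

The five bundled parameter sets (`nonadapting`, `adapting_firing`,
`adapting_to_silent`, `typeA`, `typeB`) are synthetic stand-ins calibrated
within this package to express the five published SCN cell-class
phenotypes; their files say so explicitly.

A thin CLI mirrors the library for shell use
(`scnmodel simulate|features|fit|pareto|sweep|synth`); run
`scnmodel --help`.

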