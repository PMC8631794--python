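# Methods

## The model

`scnmodel` implements a single-compartment conductance-based (Hodgkin-Huxley
type) model of a suprachiasmatic-nucleus (SCN) neuron:

    C dV/dt = I_app(t) - I_Na - I_K - I_Ca - I_LNa - I_LK - I_H - I_A
              - I_synE - I_synI

with transient sodium `I_Na = g_Na mNa_inf(V)^3 hNa (V - E_Na)`, delayed
rectifier `I_K = g_K n^4 (V - E_K)`, transient calcium
`I_Ca = g_Ca mCa hCa (V - E_Ca)`, separate sodium and potassium leaks, a
hyperpolarization-activated cation current `I_H = g_H mH (V - E_H)`, a
transient subthreshold A-type potassium current
`I_A = g_A mA_inf(V)^3 hA (V - E_K)`, and GABAergic synaptic currents
`I_syn = g_syn s(t) (V - E_syn)` of either polarity gated by an external
waveform.  All gating variables share one uniform kinetic form,

    q_inf(V) = 1/2 + 1/2 tanh((V - v_q)/dv_q)
    tau_q(V) = tau_q0 + tau_q1 (1 - tanh^2((V - v_q)/dv_q))

with inactivation encoded by a negative slope width `dv_q`.  The time
constant shares its center and width with the steady state; a per-gate
override (`v_half_tau`, `dv_tau`) exists but is unset by default, because
the shared form is the uniform convention this model family uses.  Sodium
and A-type activation are instantaneous (evaluated at the current voltage),
which removes two stiff states with little effect on spike shape at SCN
firing rates.  Units are mV, ms, pA, nS, pF throughout; these are mutually
consistent (pF·mV/ms = pA = nS·mV), so the code contains no unit
conversions.

Three dimensionless scaling factors expose the mechanism experiments
without touching the underlying parameters: `sf_gA` multiplies g_A,
`sf_tau_hA` multiplies tau_hA(V), and `sf_leak` divides g_LNa while
multiplying g_LK.  `sf_leak` is the circadian "bicycle" knob: values below
1 model the daytime up-state (more sodium leak, less potassium leak),
values above 1 the night-time down-state.

## Numerical integration

Protocols are piecewise-constant current injections.  The integrator
(`simulation.integrate`) restarts the stiff adaptive solver (LSODA,
rtol 1e-8, atol 1e-10 by default) at every protocol breakpoint, so the
discontinuous applied current is represented exactly rather than smeared
across a step.  Output is sampled on a uniform grid (default 0.04 ms,
the 25 kHz rate of the recordings this mimics).  Spike detection is an
upward crossing of -20 mV with a 2 ms refractory, linearly interpolated
between samples; the threshold is deliberately low because SCN action
potentials are small.  Resting behavior is classified by integrating 10 s
and inspecting the terminal window: < 0.5 mV peak-to-peak is treated as a
fixed point and polished by Newton root-finding on the right-hand side
(residual below 1e-6); anything else is summarized as an oscillation with
rate, period and voltage range.  Firing rates in f-I curves discard the
first 2 s of each constant-current epoch (adaptation time scales in the
bundled cells are well under 2 s) and count spikes over a 5 s window by
default.

## Feature extraction choices

RMP is the 30 s mean voltage with spikes included (a spike-masked variant
exists but is not the default); SFR counts spikes over the same window.
Input resistance uses steady-state windows (the last 100 ms of the -30 pA
pulse against the 100 ms before it, spikes masked) because transient
charging would bias Ohm's law.  Adaptation classes use a 0.75
second-half/first-half rate ratio and a 20 % amplitude-decline threshold;
the decline is measured robustly as one minus the ratio of the median
amplitude of the final spikes to the median first-half amplitude, so a
single oversized onset spike (common when a cell rests far below
threshold) does not masquerade as adaptation.  The Type-B latency
threshold is 150 ms - between the shortest delay observed in delay-type
cells (160 ms) and the latency after pharmacological A-current blockade
(~86 ms).  All thresholds are configurable and every classifier reports
the evidence values it used.

## Parameter estimation (variational assimilation with nudging)

Current-clamp data observe only V(t); the six gating states and most
parameters are hidden.  The estimator treats this as a strongly-constrained
variational problem regularized by nudging, in two stages.

**Stage 1 - strong-nudging limit.**  If the voltage trajectory is pinned
to the data, each gating ODE becomes a scalar linear ODE driven by the
measured voltage and is integrated exactly (exponential update per sample
step at the midpoint voltage).  The only remaining residual is the
trapezoidal defect of the membrane equation along the data,

    u_i = C (V_{i+1} - V_i)/dt - (1/2)(f_i + f_{i+1}),

which is precisely the additive control that would be needed to hold the
model on the measurements - the nudging input.  Minimizing sum(u_i^2) over
the free parameters is a linear least-squares problem whenever only
maximal conductances are free (each defect is affine in the conductances),
and a small bounded nonlinear least-squares problem when kinetic
parameters are free.  On noise-free data from the model itself the defect
at the true parameters is pure discretization error, so recovery is exact
to high order.

**Stage 2 - nudging relaxation (optional, `stage2=True`).**  Starting from
the stage-1 estimate, the model is simulated with an explicit nudging
control u(t) = g (V_data - V) and the objective adds a penalty
lambda·mean(u^2).  Over the schedule ((0.5, 1), (0.1, 10), (0.02, 100))
the gain g falls while the penalty weight lambda rises geometrically, with
warm starts between stages, driving the control toward zero so the final
model must track the data free-running rather than by being steered.

Multistart (default 50 starts) draws free parameters uniformly within
bounds from per-start seeds derived deterministically from the master
seed; hidden states start from the data voltage with gating at steady
state.  Model selection computes, for every candidate, the assimilation
cost and the mean absolute firing-rate mismatch over validation protocols
simulated free-running, takes the exact non-dominated (Pareto) set, and
selects the candidate closest to the ideal point after normalizing both
objectives to [0, 1]; ties break toward lower assimilation cost.  Final
reported models are always evaluated free-running - the quantity that
matters is simulation-versus-data, not the constrained-fit residual.

This two-stage scheme was chosen over a full direct transcription (states
at every node as decision variables solved by an interior-point NLP)
because the latter needs a large-scale sparse NLP solver; the stage-1
limit is the same collocation residual with the state pinned to data, and
stage 2 restores the finite-nudging behavior of the full formulation.
Twin experiments (below) are the validation that the scheme recovers
parameters.

## Bundled cells (synthetic stand-ins)

The five named parameter sets under `scnmodel/fixtures/` are synthetic:
they were calibrated within this package to reproduce the qualitative
phenotypes of the five published cell classes, plus those printed
per-channel magnitudes that the calibration could reach, and are labelled
`synthetic_` to make that explicit.  They are not transcriptions of any
deposited parameter set.  Common design: C = 5.7 pF, E_Na = +45 mV,
E_K = -97 mV, total leak 0.5 nS (R_input 2 GOhm, inside the recorded
0.84-4.47 GOhm range), and a persistent-sodium pacemaking mechanism - the
sodium inactivation time constant is large (hundreds of ms) in the
subthreshold band and fast elsewhere, so recovery of hNa paces the
interspike interval, consistent with the known role of persistent sodium
in SCN pacemaking.

- **nonadapting**: g_K = 102 nS with a steep activation curve positioned
  so n_inf(-13 mV) = 0.93.  The strong subthreshold potassium window near
  -35 mV prevents depolarization block, so a +30 pA pulse evokes sustained
  firing.
- **adapting_firing**: g_K = 43 nS with the activation curve flattened so
  that n_inf(-13 mV) = 0.5.  The weak delayed rectifier under-repolarizes
  each action potential, sodium stays partially inactivated, and spike
  amplitude declines ~45 % across the pulse while firing continues.
- **adapting_to_silent**: g_K = 28 nS, slightly flatter still; the
  potassium window cannot hold the pulse plateau below the sodium
  inactivation cliff, so the cell fires only at pulse onset and then sits
  in depolarization block until release.
- **typeA**: the basic spiking cell with a transient calcium current whose
  inactivation (hCa) de-inactivates during a hyperpolarizing pulse,
  producing a rebound spike and a transient post-pulse rate elevation.
- **typeB**: typeA plus A-type potassium (slow inactivation, tau_hA0 =
  140 ms, in the physiological range associated with delay-to-fire
  behavior) and a small H current (the depolarizing sag).  After a 1 s
  -30 pA pulse the de-inactivated A-current holds the cell below threshold
  for ~0.75 s at sf_gA = 1; zeroing sf_gA (the in-silico 4-AP experiment)
  converts the response to a Type-A rebound.

The calibration could not reproduce every printed magnitude.  In
particular the peak sodium current during a +30 pA pulse exceeds the
published value for the non-adapting class (the first pulse-evoked spike
fires from nearly fully recovered sodium in these stand-ins, where the
published models rest closer to threshold with partially inactivated
sodium), and the adapting cells here rest silent rather than tonically
firing.  The per-class potassium magnitudes (I_K, G_K), the gating-curve
values, and all directional/mechanistic behaviors are reproduced; the
acceptance report states which quantities those are.

## Synthetic data

`synth.generate_recording` integrates a model under a protocol and adds
iid Gaussian noise to the voltage only (default experiments use
sd = 0.25 mV); there is no process noise because the model is
deterministic and the assimilation cost penalizes voltage misfit.  The
synaptic gating stand-in is a Poisson event train with unit instantaneous
rise, exponential decay and clipping to [0, 1]; the real PSC-derived
waveforms are not tabulated anywhere reusable, so all synaptic-map
contracts in this package are directional, not value-matched.  The
conductance-map default drive is dense and brief (80 Hz, tau = 2 ms):
with unit-amplitude events, sparser or longer-lived drives produce
conductance transients large enough to push these small cells toward
depolarization block, inverting the sign of "excitatory" input.  Populations jitter each maximal conductance by a
uniform factor (default 0.9-1.1) around a base cell and assign sf_leak
below 1 to day cells and above 1 to night cells.  Every generator is a
pure function of (spec, seed).

What passing tests on these data do and do not show: they validate the
estimation machinery, the feature extraction and the mechanism sweeps
against data whose generating process is exactly the model class being
fitted, with ideal white voltage noise.  Real recordings contain channel
noise, synaptic bombardment, electrode artifacts and slow drift that these
twins do not emulate, so twin-experiment recovery quantifies algorithmic
correctness, not expected accuracy on tissue data.

## Problem sizes and defaults

Default problem sizes keep every analysis comfortably interactive on one
core: assimilation windows of 1-2 s decimated to 0.25 ms nodes (a few
thousand nodes per window), 10-50 multistarts, 10 s settle simulations,
5 s rate windows, latency grids of 5-7 points per axis.  All are
parameters, not constants.

## Known limitations

- No BK current, calcium subtypes, intracellular calcium dynamics, channel
  noise or temperature corrections (outside the model class by design).
- The leak is ohmic, so a -30 pA pulse into a 2 GOhm cell hyperpolarizes
  the basic model well below the range real cells visit (real membranes
  rectify); the typeB cell's H current partially counteracts this.
- The ABF importer reads the ABF v1 fixed-header layout (gap-free and
  episodic, int16 and float32); ABF2 files are rejected explicitly rather
  than half-parsed.
- `find_resting_behavior` classifies by simulation; it cannot distinguish
  a very-long-transient from a sustained oscillation, and onset
  classification in `spiking_onset_scan` is simulation-based (amplitude
  growth and hysteresis), deliberately avoiding numerical continuation.
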