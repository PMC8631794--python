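"""Twin experiment: recover conductances from synthetic current-clamp data.

Generates noise-free recordings from the bundled non-adapting cell under
depolarizing and hyperpolarizing pulses, then estimates g_Na and g_K from
those traces alone and prints the relative recovery errors.
"""

from scnmodel import load_fixture
from scnmodel.assimilation import build_problem, get_param, solve
from scnmodel.simulation import SolverOptions, StimulusProtocol
from scnmodel.synth import NoiseSpec, generate_recording

truth = load_fixture("nonadapting")
opts = SolverOptions(rtol=1e-7, atol=1e-9, output_dt_ms=0.1)
protocols = [
    StimulusProtocol.single_pulse(30.0, 500.0, 1000.0, 2000.0),
    StimulusProtocol.single_pulse(-30.0, 500.0, 1000.0, 2000.0),
]
traces = [generate_recording(truth, pr, NoiseSpec(0.0, 0), opts) for pr in protocols]

problem = build_problem(traces, {"base": truth, "free": ["g_Na", "g_K"]})
results = solve(problem, n_starts=3, seed=42)
best = results[0]

print("twin-experiment recovery (noise-free, {g_Na, g_K} free):")
for name in ("g_Na", "g_K"):
    true = get_param(truth, name)
    est = best.values[name]
    print(f"  {name}: true {true:7.2f} nS   estimated {est:7.2f} nS   "
          f"relative error {abs(est - true) / true:.2e}")
print(f"assimilation cost (mean squared equation defect): {best.cost:.3e} pA^2")
print("Recovery errors at the few-percent level are discretization-limited:")
print("the residual left at the true parameters is the trapezoidal defect of")
print("the membrane equation across action potentials, not model mismatch.")
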