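"""Classify evoked responses of the bundled cell classes.

Runs the standard +30 pA and -30 pA 1 s pulses on each bundled parameter
set and prints the adaptation class and the hyperpolarizing-pulse
(rebound vs delay-to-fire) classification with its evidence.
"""

from scnmodel import (SolverOptions, available_fixtures,
                      classify_depolarizing_response, find_resting_behavior,
                      integrate, load_fixture, measure_delay_to_fire)
from scnmodel.simulation import StimulusProtocol

opts = SolverOptions(rtol=1e-6, atol=1e-8, output_dt_ms=0.05)
dep = StimulusProtocol("dep", 0.0, ((1000.0, 1000.0, 30.0),), 3000.0)
hyp = StimulusProtocol("hyp", 0.0, ((2000.0, 1000.0, -30.0),), 8000.0)

for name in available_fixtures():
    cell = load_fixture(name)
    rest = find_resting_behavior(cell, 0.0, options=opts)
    init = rest.state if rest.mode == "fixed-point" else rest.cycle.meta["final_state"]

    ev_dep = classify_depolarizing_response(integrate(cell, dep, init, opts))
    ev_hyp = measure_delay_to_fire(integrate(cell, hyp, init, opts))
    lat = (f"{ev_hyp.delay_latency_ms:.0f} ms" if ev_hyp.delay_latency_ms
           else "undefined")
    print(f"{name:20s} depolarizing: {ev_dep.depolarizing_class or 'unclassifiable':20s}"
          f" hyperpolarizing: {ev_hyp.hyperpolarizing_class or '-':7s} latency {lat}")

print()
print("Sustained firing marks non-adapting cells; amplitude decline with")
print("continued firing marks adapting-firing; early silence marks")
print("adapting-to-silent.  After hyperpolarization, rebound spiking is the")
print("Type-A response and a long delay-to-fire the Type-B response.")
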