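"""Simulate a spontaneously firing SCN model cell and measure its passive properties.

Loads the bundled non-adapting cell, finds its resting behavior, runs the
standard input-resistance pulse (-30 pA, 500 ms), and prints resting
membrane potential (RMP), spontaneous firing rate (SFR), and input
resistance (R_input) the way a current-clamp experimenter would report
them.
"""

from scnmodel import (SolverOptions, find_resting_behavior, integrate,
                      load_fixture, measure_input_resistance, measure_rmp_sfr,
                      standard_protocols)

cell = load_fixture("nonadapting")
opts = SolverOptions(rtol=1e-6, atol=1e-8, output_dt_ms=0.1)

rest = find_resting_behavior(cell, I_app=0.0, options=opts)
print(f"resting behavior: {rest.mode}, spontaneous rate {rest.rate_hz:.2f} Hz")

# 35 s at zero current for the 30 s RMP/SFR windows
from scnmodel.simulation import StimulusProtocol
hold = StimulusProtocol.constant(0.0, 35_000.0)
init = rest.state if rest.mode == "fixed-point" else rest.cycle.meta["final_state"]
trace = integrate(cell, hold, init, opts)
rmp, sfr = measure_rmp_sfr(trace, window_ms=30_000.0)
print(f"RMP = {rmp:.1f} mV (30 s mean, spikes included), SFR = {sfr:.2f} Hz")

pulse = standard_protocols()["r_input"]
tr = integrate(cell, pulse, init, opts)
pp = measure_input_resistance(tr)
print(f"R_input = {pp.R_input_GOhm:.2f} GOhm (Ohm's law on the -30 pA / 500 ms pulse)")
print("A moderately depolarized, tonically firing cell with gigaohm input")
print("resistance is the typical daytime SCN phenotype.")
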