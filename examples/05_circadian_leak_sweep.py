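"""The circadian leak "bicycle": sweeping the K/Na leak ratio.

An antiphase rhythm in sodium versus potassium leak sets the SCN's daily
excitability cycle.  Scaling factors below 1 (more Na leak, less K leak)
model the daytime up-state; above 1, the night-time down-state.
"""

from scnmodel.behavior import leak_scaling_sweep
from scnmodel.fixtures import load_fixture

# the delay-type cell traverses the whole range without
# depolarization block (its A-current opposes it)
cell = load_fixture("typeB")
res = leak_scaling_sweep(cell, sf_values=(0.85, 0.925, 0.95, 1.0, 1.05, 1.15),
                         settle_ms=8000.0)
print("sf_leak   phase        state                 rate (Hz)")
for r in res.records:
    print(f"  {r['sf_leak']:.3f}  {r['phase']:10s}  {r['state']:20s}  {r['rate_hz']:6.2f}")
print()
print("Moving from the daytime up-state toward the night down-state the cell")
print("slows and ultimately silences - the single-cell signature of the")
print("day-active/night-quiet rhythm in clock output.")
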