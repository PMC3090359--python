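"""Run one simulation of the calibrated control condition at reduced
scale and print its output metrics.

The control condition keeps the sVEGFR-1/VEGF ratio at 1/5 (the
baseline observed in vitro). Here it is shrunk to a 100x100 grid with
proportional entity counts so the example finishes in a couple of
seconds; the full-size control is `sproutsim.CONTROL`.
"""

from sproutsim import SimulationConfig, run_simulation

config = SimulationConfig(
    rows=100, cols=100, ini_ec=100,
    n_vegf=4444, n_svegfr1=889,          # same densities as the control
    num_cycles=100, p_execute=0.05, ruleset="R1", seed=7,
)
result = run_simulation(config)

print(f"final EC count : {result.final_ec_count}")
print(f"vessel area    : {result.area:.4f}   (numECs / gridArea)")
print(f"network reach  : {result.reach} sites above the initial vessel")
# The EC count only ever grows (no cell death in the model), so the
# area is the cumulative footprint of the sprouting network; reach is
# how far the farthest branch tip got from the bottom-row vessel.
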