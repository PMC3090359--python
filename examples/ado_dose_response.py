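"""Dose-response of vessel network area to added adenosine.

Runs a scaled-down version of the added-Ado experiment (ruleset R2:
adenosine licenses EC division regardless of the sVEGFR-1 veto) and
contrasts each dose with the control batch by a Welch t-test.
"""

from sproutsim import (
    BatchSpec, SimulationConfig, compare_to_control, run_batch, sweep,
)

# 100x100 grid with control-density VEGF and sVEGFR-1; Ado counts are
# scaled the same way (full-scale doses would be 9x larger).
base = SimulationConfig(
    rows=100, cols=100, ini_ec=100,
    n_vegf=4444, n_svegfr1=889, num_cycles=100, ruleset="R2", seed=0,
)
spec = BatchSpec(base, num_sim=10, base_seed=0)

results = sweep(spec, "n_ado", [0, 220, 440, 890, 1780])
control = results[0][1]

print(f"{'Ado':>6} {'mean area':>10} {'vs control p':>13}")
for ado, batch in results:
    p = "-" if batch is control else f"{compare_to_control(batch, control).p_value:.1e}"
    print(f"{ado:>6} {batch.mean_area:>10.4f} {p:>13}")
# Expected shape: mean area rises with the Ado dose and the increase
# becomes significant well below saturation, mirroring the pro-angiogenic
# modulation hypothesis encoded in ruleset R2.
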