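"""Compare the power of the three designs on shared simulated data.

Every replicate simulates one N-of-1 cohort; the crossover design reuses the
first cycle and the parallel RCT one randomly chosen first-cycle period, so
all three designs are judged on identical outcome draws.  With a moderate
effect (tau = 0.25) and 30 patients the aggregated N-of-1 design is far more
powerful than either single-observation-per-condition design.
"""

from nof1sim import SimulationModel, run_oc

model = SimulationModel.scenario(1, tau=0.25)
B = 400  # replicates; increase for smoother estimates

print("power to detect tau = 0.25 at n = 30 (scenario 1):")
for design in ("nof1", "crossover", "rct"):
    res = run_oc(model, design, n=30, B=B, seed=2024)
    print(f"  {design:10s} {res.rejection_rate:5.1%}  (MC se {res.mc_se:.3f})")
print("-> the same cohorts analyzed three ways; more within-patient periods,")
print("   more power at the same number of patients")
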