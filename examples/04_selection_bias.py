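"""False-positive rate when the sample is not representative of the target.

Each patient is drawn from the target population (no true effect, tau = 0)
with probability p and from a responding sub-population (tau = 0.25)
otherwise.  Any rejection is a false conclusion about the target
population.  The N-of-1 design, with six observations per patient, amplifies
the contamination far more than the single-period parallel RCT.
"""

from nof1sim import SimulationModel, selection_bias_oc

model = SimulationModel.scenario(1)
B, n = 400, 30
print("type-I error for the target population (n = 30, scenario 1):")
print(f"  {'p':>4s}  {'rct':>6s}  {'crossover':>9s}  {'nof1':>6s}")
for p in (1.0, 0.7, 0.5):
    row = {}
    for design in ("rct", "crossover", "nof1"):
        res = selection_bias_oc(model, design, n, [p], B, seed=31, mode="type1")[0]
        row[design] = res.rejection_rate
    print(f"  {p:4.1f}  {row['rct']:6.1%}  {row['crossover']:9.1%}  {row['nof1']:6.1%}")
print("-> at p=1 all designs hold the nominal 5%; as contamination grows the")
print("   repeated-measures designs over-reject most")
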