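"""Spotting a responding sub-population through predicted random intercepts.

With a half-contaminated sample (target tau = 0, sub-population tau = 0.25)
the patient-level BLUPs from the treatment model absorb part of the
sub-population's extra response.  The difference in mean BLUP between the
two groups is positive and much sharper under the N-of-1 design (six periods
per patient) than under the crossover (two periods) -- the parallel RCT
cannot estimate patient-level effects at all.
"""

from nof1sim import SimulationModel, compare_random_effects

model = SimulationModel.scenario(1, tau=0.0, tau_sub=0.25)
nof1, xo = compare_random_effects(model, n=100, p=0.5, B=200, seed=41)
for comp in (nof1, xo):
    print(
        f"{comp.design:10s} mean BLUP difference (sub - target) "
        f"{comp.mean_diff:+.4f} (se {comp.se_diff:.4f}), "
        f"positive in {comp.separation:.0%} of replicates"
    )
print("-> a consistently positive difference flags patients who are unlike the")
print("   target population; the N-of-1 design separates them more reliably")
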