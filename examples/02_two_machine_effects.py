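"""Per-subject counterfactual risk effects with the two-machine method.

One machine is trained on the X3 = 0 subjects and one on the X3 = 1
subjects; every subject is scored by both, giving an observed and a
counterfactual success probability from which the risk difference,
risk ratio and odds ratio follow per subject.
"""

import riskmachines as rm

data = rm.simulate(rm.builtin_model("model1"), n=1000, seed=11)
pair = rm.two_machine(data, target="X3", seed=12)
est = rm.aggregate(rm.effect_functions(pair))

print(f"training subgroups: |D0| = {pair.n0}, |D1| = {pair.n1}")
print(f"median odds ratio   OR = {est.aggregate_or:.3f}   (true conditional OR: 2.0)")
print(f"median risk ratio   RR = {est.aggregate_rr:.3f}")
print(f"median risk diff    RD = {est.aggregate_rd:.3f}")

# subgroup effects come from the same per-subject vectors, no refitting
mask = data.column("X2") == 1
sub = rm.aggregate(est, subgroup=mask)
print(f"median OR among X2 = 1 subjects: {sub.aggregate_or:.3f}")

print(
    "\nThe aggregate OR estimates the effect of flipping X3 with every other\n"
    "feature held at each subject's own values; a single replicate scatters\n"
    "around the truth, and the replicate median (see the study harness)\n"
    "recovers it."
)
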