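"""A small replicate study: RFPM versus logistic comparators.

Repeatedly simulates data with two unmodeled interactions (model 2),
fits a main-effects logistic regression (LR1), a logistic regression
with all pairwise interactions (LR2) and an RFPM per replicate, and
summarizes bias and 5th-95th percentile width of the probability
estimates on a fixed evaluation set. Thirty replicates keep this quick;
the defaults in the harness use 200.
"""

import riskmachines as rm

cfg = rm.StudyConfig(model="model2", n=1000, reps=30, seed=41, eval_n=300)
res = rm.probability_study(cfg)

g = res.per_stratum.groupby("method")
print("method   worst-stratum |bias|   mean 5th-95th width")
for method in ("LR1", "LR2", "RFPM"):
    bias = g.get_group(method)["bias"].abs().max()
    width = g.get_group(method)["mean_width"].mean()
    print(f"{method:<6}   {bias:18.3f}   {width:19.3f}")
print(f"(non-converged comparator fits flagged: {len(res.failures)})")

print(
    "\nLR1 omits the generating interactions, so its worst-stratum bias is\n"
    "an order of magnitude above the RFPM's; the RFPM pays for its\n"
    "flexibility with widths between LR1's and LR2's. Export with\n"
    "rm.export(res, 'out/study') for the tidy CSV + JSON summary."
)
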