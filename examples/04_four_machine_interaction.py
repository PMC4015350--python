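"""Estimate an interaction odds ratio with the 4-machine method.

One machine per observed (X1, X2) cell gives each subject four
probabilities (p00, p01, p10, p11) - one observed, three
counterfactual - whose ratio of odds ratios estimates the
multiplicative interaction per subject.
"""

import numpy as np

import riskmachines as rm

data = rm.simulate(rm.builtin_model("model5"), n=1000, seed=31)
res = rm.four_machine(data, "X1", "X2", seed=32)

print("cell training sizes:", {k: v for k, v in sorted(res.cell_sizes.items())})
print(f"median interaction odds ratio: {res.aggregate_ior:.3f}  (true: 2.0)")
print(f"median additive contrast:      {res.aggregate_additive:+.4f}")
print(f"per-subject ior spread (5th-95th pct): "
      f"{np.percentile(res.ior, 5):.2f} .. {np.percentile(res.ior, 95):.2f}")

print(
    "\nA single replicate's median ior scatters around the true ratio of 2\n"
    "(the replicate median across 200 simulations recovers it; see the\n"
    "study harness). The additive contrast is the same four probabilities\n"
    "combined on the probability scale - the framework is not tied to the\n"
    "multiplicative scale."
)
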