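"""Keystone-taxon inference by refined structural path modeling.

Simulates a locus whose genotype shifts three taxa, which in turn
drive a diversity axis, plus two deliberately spurious paths.  After
collapsing every variable into four ordinal quantiles, backward
refinement removes non-significant paths one at a time; taxa whose
path into the diversity axis survives are the candidate keystones.
"""

import numpy as np
import pandas as pd

from microqtl import path_model as pm

rng = np.random.default_rng(12)
n = 500
g = rng.choice([0.0, 1.0, 2.0], n, p=[0.25, 0.5, 0.25])  # F2 locus dosage
shared = rng.normal(size=n)
t1 = 0.45 * (g - 1) + 0.5 * shared + 0.75 * rng.normal(size=n)
t2 = 0.40 * (g - 1) + 0.5 * shared + 0.75 * rng.normal(size=n)
t3 = 0.35 * (g - 1) + rng.normal(size=n)
div = 0.40 * t1 + 0.35 * t2 + 0.35 * t3 + 0.8 * rng.normal(size=n)
data = pd.DataFrame({"locus": g, "taxon1": t1, "taxon2": t2, "taxon3": t3,
                     "diversity": div})

spec = pm.PathModelSpec(
    variables=list(data.columns),
    directed_paths=[
        ("locus", "taxon1"), ("locus", "taxon2"), ("locus", "taxon3"),
        ("taxon1", "diversity"), ("taxon2", "diversity"), ("taxon3", "diversity"),
        ("locus", "diversity"),            # spurious: no direct effect simulated
    ],
    covariance_paths=[("taxon1", "taxon2"),  # true shared environment
                      ("taxon2", "taxon3")], # spurious
)

fit = pm.refine_path_model(spec, data)
print(f"refinement removed {len(fit.refinement_trace)} path(s):")
for step in fit.refinement_trace:
    arrow = "->" if step["kind"] == "directed" else "~~"
    print(f"  dropped {step['removed'][0]} {arrow} {step['removed'][1]} "
          f"(p = {step['p_value']:.3f})")

print("\nretained paths (standardized coefficient on ordinal scores, p-value):")
print(fit.to_frame().to_string(index=False))
parents = {s for (s, t) in (p.edge for p in fit.paths if p.kind == "directed")
           if t == "diversity"}
keystones = sorted(p for p in parents if p.startswith("taxon"))
print(f"\ncandidate keystone taxa (paths into diversity survive): {keystones}")
if "locus" in parents:
    print("note: the spurious direct locus->diversity path survived refinement —")
    print("ordinal binning attenuates the taxa, letting the locus pick up a small")
    print("residual effect; backward elimination admits occasional edges like this.")
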