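"""Simulate a complete F2 microbiome-QTL study with known ground truth.

Builds a genetic map over 19 autosomes, an F2 population from two
inbred founders (Haldane recombination, 1:2:1 segregation), sex/diet
covariates, a random rooted phylogeny and a zero-inflated
negative-binomial ASV count table with planted QTL, then prints the
planted truth so you can see what a downstream scan should find.
"""

import numpy as np

import microqtl as mq

cfg = mq.StudyConfig(
    n_individuals=469,
    n_chromosomes=19,
    markers_per_chromosome=20,
    n_asvs=80,
    seed=42,
)
bundle = mq.make_study(cfg)

geno = bundle.genotypes.genotypes
freqs = np.bincount(geno.ravel(), minlength=3) / geno.size
print(f"individuals: {bundle.genotypes.n_samples}, markers: {bundle.map.n_markers}, "
      f"ASVs: {bundle.counts.n_asvs}")
print(f"genotype frequencies (expect ~0.25/0.50/0.25): {np.round(freqs, 3)}")
print(f"median library size: {np.median(bundle.counts.sample_totals()):.0f} reads")

print("\nplanted QTL (what a scan should recover):")
for e in bundle.planted_qtl():
    kind = e.interaction_mode if e.interaction_mode != "none" else "marginal"
    size = e.additive_effect or e.interaction_effect
    print(f"  {e.trait_id}: {kind} effect {size:+.2f} (log scale) at {e.qtl_marker}")
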