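"""From raw ASV counts to linkage-ready diversity traits.

Rarefies the count table to a fixed depth, computes Shannon diversity
and observed species, builds the four beta-diversity distance matrices,
ordinates each by PCoA and extracts PCo1/PCo2 as quantitative traits —
the same trait set a genome scan consumes.
"""

import microqtl as mq
from microqtl import diversity as dv

bundle = mq.make_study(
    mq.StudyConfig(n_individuals=150, n_chromosomes=3, markers_per_chromosome=10,
                   n_asvs=60, library_size_mean=9000.0, seed=7)
)

rarefied, dropped = dv.rarefy(bundle.counts, depth=4500, seed=7)
print(f"rarefied to 4500 reads/sample; {len(dropped)} sample(s) below depth dropped")

alpha = dv.alpha_diversity_table(rarefied)
print(f"Shannon diversity: mean {alpha['shannon'].mean():.2f} bits, "
      f"observed species: mean {alpha['observed_species'].mean():.1f}")

pcoas = {}
for name, dm in (
    ("bray_curtis", dv.bray_curtis(rarefied)),
    ("jaccard", dv.jaccard(rarefied)),
    ("unweighted_unifrac", dv.unweighted_unifrac(rarefied, bundle.tree)),
    ("weighted_unifrac", dv.weighted_unifrac(rarefied, bundle.tree)),
):
    pcoas[name] = dv.pcoa(dm)
    pe = pcoas[name].proportion_explained
    print(f"{name}: PCo1 explains {100 * pe[0]:.1f}%, PCo2 {100 * pe[1]:.1f}% "
          "of the (positive-eigenvalue) variation")

traits = dv.eigenvector_traits(pcoas, axes=[1, 2], alpha_traits=alpha)
print(f"\ntrait columns for linkage analysis ({traits.shape[1]}):")
print(" ", ", ".join(traits.columns))
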