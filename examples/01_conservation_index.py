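"""Rank conservation: how stable is the gene ordering within a phenotype?

Generates a small two-phenotype study, computes the per-network rank
conservation index mu_R for each phenotype, and summarises global
regulation.  mu_R near 1 means the network's genes keep one ordering
across samples (tight regulation); near 0.5 the orderings shuffle freely.
"""

from diracnet import conservation_table, global_conservation
from diracnet.synth import SynthSpec, generate_study

spec = SynthSpec(n_networks=6, n_discriminative=2, sigma=0.5, seed=1)
study, networks, truth = generate_study(spec)

table = conservation_table(study, list(networks))
print("Rank conservation index mu_R (rows: networks, columns: phenotypes)")
print(table.round(3))

means, anova_p = global_conservation(table)
print("\nGlobal regulation (mean mu_R per phenotype, tightest first):")
for phenotype, mean in means.items():
    print(f"  {phenotype}: {mean:.3f}")
print(f"one-way ANOVA p-value across phenotypes: {anova_p:.3g}")
print(
    "\nAll values sit well above 0.5: at noise sigma = delta/2 the base\n"
    "ordering dominates, so each network keeps a stable template in both\n"
    "phenotypes; the discriminative networks differ in *which* ordering\n"
    "they keep, not in how tightly they keep it."
)
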