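"""Network deregulation: which networks lose rank conservation in disease?

The statistic is theta(m) = |mu_R(m, A) - mu_R(m, B)|, permutation-tested
by shuffling phenotype labels and re-estimating both templates each time.
Significantly deregulated networks are then counted by which phenotype
holds them more tightly, and a one-sided sign test asks whether
deregulation preferentially hits one phenotype — the pattern seen when
comparing less and more malignant disease states.
"""

import numpy as np
import pandas as pd

from diracnet import (
    ExpressionStudy,
    GeneNetwork,
    binomial_deregulation_pvalue,
    count_deregulated,
    deregulation_test,
)

# Build a study in which phenotype B is noisier (loosely regulated) in 8 of
# 12 networks: a planted one-sided deregulation signal.
rng = np.random.default_rng(3)
n_genes, n_networks, n_per_class = 8, 12, 25
blocks, networks = [], []
for m in range(n_networks):
    means = np.arange(n_genes, 0, -1, dtype=float)
    sigma_b = 2.5 if m < 8 else 0.4
    block_a = means[:, None] + rng.normal(0, 0.4, (n_genes, n_per_class))
    block_b = means[:, None] + rng.normal(0, sigma_b, (n_genes, n_per_class))
    blocks.append(np.hstack([block_a, block_b]))
    genes = tuple(f"NET{m:02d}G{g}" for g in range(n_genes))
    networks.append(GeneNetwork(name=f"NET{m:02d}", genes=genes))
values = pd.DataFrame(
    np.vstack(blocks),
    index=[g for net in networks for g in net.genes],
    columns=[f"S{j:03d}" for j in range(2 * n_per_class)],
)
study = ExpressionStudy(values).with_labels(
    ["A"] * n_per_class + ["B"] * n_per_class
)

report = deregulation_test(study, networks, ("A", "B"),
                           n_permutations=1000, seed=0)
print("Deregulation test (theta = |mu_R(A) - mu_R(B)|), top rows:")
print(report.table[["mu_A", "mu_B", "theta", "p_value", "fdr"]]
      .sort_values("theta", ascending=False).head(5).round(4))

k_less, k_more = count_deregulated(report, "A", "B", alpha=0.05)
p_sign = binomial_deregulation_pvalue(k_less, k_more, tail="strict")
print(f"\nsignificant networks tighter in A: {k_less}, tighter in B: {k_more}")
print(f"one-sided sign-test p-value: {p_sign:.3g}")
print(
    "\nA small sign-test p-value says deregulation is one-sided: the\n"
    "networks that lost rank conservation all lost it in phenotype B,\n"
    "as planted."
)
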