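"""Classifying samples by rank templates, honestly cross-validated.

Trains the single-best-network DIRAC classifier (largest apparent
classification rate eta on training data; predict A iff the rank
difference score Delta > 0) and estimates its generalisation rate by
leave-one-out cross-validation, where template estimation and network
selection are repeated inside every split.  The size-matched top-scoring
pair (TSP) comparator runs on Wilcoxon-filtered genes.
"""

from diracnet import loocv, train_dirac
from diracnet.synth import SynthSpec, generate_study

spec = SynthSpec(
    n_networks=10, n_discriminative=1, n_samples_a=15, n_samples_b=15,
    sigma=0.5, seed=6,
)
study, networks, truth = generate_study(spec)
print(f"planted discriminative network: {truth.discriminative[0]}")

model = train_dirac(study, list(networks), ("A", "B"))
print(f"selected network: {model.network.name} "
      f"(apparent eta = {model.apparent_eta:.3f})")
print(f"template Hamming distance between phenotypes: "
      f"{(model.template_a.bits != model.template_b.bits).sum()} "
      f"of {len(model.template_a.bits)} pairs")

for method in ("dirac", "tsp"):
    result = loocv(study, list(networks), ("A", "B"), method=method, seed=0)
    print(f"{method} LOOCV rate (avg of sensitivity and specificity): "
          f"{result.rate:.3f}")
print(
    "\nThe planted 20-pair template reversal separates the phenotypes, so\n"
    "the held-out rate stays near 1; a rate near 0.5 would mean the\n"
    "selected network carries no reproducible ordering difference."
)
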