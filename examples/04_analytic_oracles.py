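"""The Gaussian rank model and its closed-form conservation expectation.

Under means mu_1..mu_G with iid N(0, sigma^2) noise, each pair probability
is Pr(X_i < X_j) = Phi((mu_j - mu_i)/(sigma*sqrt(2))), so the expected
conservation index is the mean over pairs of max(p, 1-p).  This script
checks the empirical held-out mu_R against that formula across noise
levels — the parameter-recovery property the test suite relies on.
"""

import numpy as np

from diracnet import (
    conservation_index,
    estimate_template,
    expected_conservation,
    generate_phenotype,
)
from diracnet.core import encode_network

means = np.arange(9.0, -1.0, -1.0)  # 10 genes, unit gaps
print("sigma   expected mu_R   empirical mu_R (500 train / 500 held out)")
for sigma in (0.25, 0.5, 1.0, 2.0, 4.0):
    rng = np.random.default_rng(42)
    train = generate_phenotype(10, 500, means, sigma, rng)
    test = generate_phenotype(10, 500, means, sigma, rng)
    template = estimate_template(encode_network(train))
    empirical = conservation_index(encode_network(test), template)
    print(f"{sigma:5.2f}   {expected_conservation(means, sigma):13.4f}"
          f"   {empirical:14.4f}")
print(
    "\nAs noise grows relative to the unit mean gaps, conservation decays\n"
    "from 1 toward 0.5; the empirical index tracks the analytic value to\n"
    "within Monte-Carlo error at every noise level."
)
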