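import numpy as np
import pandas as pd
import pytest

from diracnet import ExpressionStudy, GeneNetwork
from diracnet.synth import SynthSpec, generate_study


def make_study(values: np.ndarray, labels=None, gene_prefix="G", sample_prefix="S"):
    """Wrap a raw (genes x samples) array in a labeled ExpressionStudy."""
    genes = [f"{gene_prefix}{i:02d}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j:03d}" for j in range(values.shape[1])]
    study = ExpressionStudy(pd.DataFrame(values, index=genes, columns=samples))
    if labels is not None:
        study = study.with_labels(list(labels))
    return study


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_network():
    return GeneNetwork(name="NET", genes=("G00", "G01", "G02", "G03"))


@pytest.fixture(scope="session")
def planted_study():
    """Default planted study: 20 networks, 3 discriminative, 30+30 samples."""
    spec = SynthSpec(seed=7)
    study, collection, truth = generate_study(spec)
    return study, list(collection), truth


@pytest.fixture(scope="session")
def null_study():
    """Two phenotypes drawn from one distribution: no real signal."""
    spec = SynthSpec(n_discriminative=0, n_networks=10, seed=11)
    study, collection, truth = generate_study(spec)
    return study, list(collection)
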