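"""Synthetic two-phenotype expression studies with known rank structure.

The generator uses a Gaussian location-shift model: gene g of a network has
a fixed base mean and every sample adds independent N(0, sigma^2) noise.
Under this model every pair probability is closed-form,

    Pr(X_i < X_j) = Phi((mu_j - mu_i) / (sigma * sqrt(2))),

which provides analytic oracles for the rank statistics: the expected
large-sample conservation index is the mean over pairs of
max(p_ij, 1 - p_ij).  Rank conservation is tuned by the ratio of the mean
gap delta to sigma; template reversals between phenotypes are planted by
permuting base means so that a prescribed number of gene pairs invert their
expected ordering.  Because all DIRAC statistics are invariant to strictly
monotone per-sample transforms, the Gaussian marginal is not a restriction
— a log-normal option exercises exactly that invariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import (
    ExpressionStudy,
    GeneNetwork,
    NetworkCollection,
    write_cls,
    write_expression_gct,
    write_gmt,
    write_table,
)

__all__ = [
    "SynthSpec",
    "generate_phenotype",
    "generate_study",
    "expected_conservation",
    "write_study",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic two-phenotype study.

    Defaults describe a moderately conserved study in which discriminative
    networks carry a strong planted reversal: 20 networks of 10 genes, 3 of
    them discriminative, 30 samples per phenotype, unit mean gap with noise
    sigma = delta/2, and 20 of the 45 gene pairs reversed in phenotype B's
    expected template.
    """

    n_genes: int = 10
    n_networks: int = 20
    n_discriminative: int = 3
    n_samples_a: int = 30
    n_samples_b: int = 30
    delta: float = 1.0            # gap between adjacent base means
    sigma: float = 0.5            # per-gene Gaussian noise scale
    n_reversed_pairs: int = 20    # planted inversions per discriminative network
    marginal: str = "gaussian"    # or "lognormal": exp-transform (rank-preserving)
    phenotype_a: str = "A"
    phenotype_b: str = "B"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0 and self.sigma <= 0:
            raise ValueError("delta and sigma cannot both be zero")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        max_pairs = self.n_genes * (self.n_genes - 1) // 2
        if not 0 <= self.n_reversed_pairs <= max_pairs:
            raise ValueError(
                f"n_reversed_pairs must be in [0, {max_pairs}]"
            )
        if self.n_discriminative > self.n_networks:
            raise ValueError("more discriminative networks than networks")

    @property
    def base_means(self) -> np.ndarray:
        """Equally spaced decreasing means: gene 0 highest."""
        return np.arange(self.n_genes - 1, -1, -1, dtype=float) * self.delta


def generate_phenotype(
    n_genes: int,
    n_samples: int,
    base_means: np.ndarray | None = None,
    sigma: float = 0.5,
    seed: int | np.random.Generator | None = None,
    delta: float = 1.0,
) -> np.ndarray:
    """One phenotype block: (genes x samples), means plus iid Gaussian noise."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if base_means is None:
        base_means = np.arange(n_genes - 1, -1, -1, dtype=float) * delta
    base_means = np.asarray(base_means, dtype=float)
    if len(base_means) != n_genes:
        raise ValueError("base_means length must equal n_genes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    noise = (
        rng.normal(0.0, sigma, size=(n_genes, n_samples))
        if sigma > 0
        else np.zeros((n_genes, n_samples))
    )
    return base_means[:, None] + noise


def _permutation_with_inversions(n: int, k: int) -> np.ndarray:
    """A permutation of range(n) with exactly k inversions (Lehmer code).

    Position i takes the remaining element ``min(k_left, n-1-i)`` steps in,
    consuming that many inversions; k = n(n-1)/2 yields the full reversal.
    """
    remaining = list(range(n))
    out = []
    left = k
    for i in range(n):
        take = min(left, n - 1 - i)
        out.append(remaining.pop(take))
        left -= take
    assert left == 0
    return np.asarray(out)


def reversed_means(base_means: np.ndarray, n_reversed_pairs: int) -> np.ndarray:
    """Permute base means so exactly that many pairs invert expected order.

    Applied to a strictly decreasing mean vector, the returned vector's
    noiseless template differs from the original's in exactly
    ``n_reversed_pairs`` bits.
    """
    perm = _permutation_with_inversions(len(base_means), n_reversed_pairs)
    return np.asarray(base_means, dtype=float)[perm]


@dataclass
class StudyTruth:
    """Ground truth of a generated study."""

    spec: SynthSpec
    discriminative: list[str] = field(default_factory=list)
    expected_bits_a: dict[str, np.ndarray] = field(default_factory=dict)
    expected_bits_b: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "network": name,
                "discriminative": name in self.discriminative,
                "expected_template_distance": float(
                    np.mean(self.expected_bits_a[name] != self.expected_bits_b[name])
                ),
            }
            for name in self.expected_bits_a
        ]
        return pd.DataFrame(rows)


def _expected_bits(means: np.ndarray) -> np.ndarray:
    from .core import enumerate_pairs

    pairs = enumerate_pairs(len(means))
    return (means[pairs[:, 0]] < means[pairs[:, 1]]).astype(np.uint8)


def generate_study(
    spec: SynthSpec,
) -> tuple[ExpressionStudy, NetworkCollection, StudyTruth]:
    """Generate a labeled study, its network collection and ground truth.

    Phenotype B reuses phenotype A's base means except in the first
    ``n_discriminative`` networks, where the means are permuted so exactly
    ``n_reversed_pairs`` gene pairs flip their expected ordering.  With a
    fixed seed the output is reproducible bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    means_a = spec.base_means
    means_b_reversed = reversed_means(means_a, spec.n_reversed_pairs)

    gene_names: list[str] = []
    networks: list[GeneNetwork] = []
    blocks_a, blocks_b = [], []
    truth = StudyTruth(spec=spec)
    for m in range(spec.n_networks):
        name = f"NET{m:03d}"
        genes = tuple(f"{name}G{g:02d}" for g in range(spec.n_genes))
        gene_names.extend(genes)
        networks.append(GeneNetwork(name=name, genes=genes))
        discriminative = m < spec.n_discriminative
        means_b = means_b_reversed if discriminative else means_a
        if discriminative:
            truth.discriminative.append(name)
        truth.expected_bits_a[name] = _expected_bits(means_a)
        truth.expected_bits_b[name] = _expected_bits(means_b)
        blocks_a.append(
            generate_phenotype(
                spec.n_genes, spec.n_samples_a, means_a, spec.sigma, rng
            )
        )
        blocks_b.append(
            generate_phenotype(
                spec.n_genes, spec.n_samples_b, means_b, spec.sigma, rng
            )
        )
    values = np.vstack(
        [np.hstack([blocks_a[m], blocks_b[m]]) for m in range(spec.n_networks)]
    )
    if spec.marginal == "lognormal":
        values = np.exp(values)  # strictly increasing: ranks unchanged
    elif spec.marginal != "gaussian":
        raise ValueError(f"unknown marginal {spec.marginal!r}")
    sample_ids = [f"S{a}{i:03d}" for a, count in
                  ((spec.phenotype_a, spec.n_samples_a),
                   (spec.phenotype_b, spec.n_samples_b))
                  for i in range(count)]
    labels = (
        [spec.phenotype_a] * spec.n_samples_a
        + [spec.phenotype_b] * spec.n_samples_b
    )
    frame = pd.DataFrame(values, index=gene_names, columns=sample_ids)
    study = ExpressionStudy(frame).with_labels(labels)
    return study, NetworkCollection(networks), truth


def expected_conservation(
    base_means: np.ndarray, sigma: float
) -> float:
    """Analytic large-sample expectation of the conservation index.

    With pair probability p_ij = Phi((mu_j - mu_i)/(sigma*sqrt(2))), the
    majority template matches each pair with probability max(p_ij, 1-p_ij);
    averaging over pairs gives the expected mu_R for a template estimated
    on infinitely many samples.  sigma -> 0 gives 1 (for distinct means);
    equal means give 0.5.
    """
    from .core import enumerate_pairs

    mu = np.asarray(base_means, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    pairs = enumerate_pairs(len(mu))
    gaps = mu[pairs[:, 1]] - mu[pairs[:, 0]]
    if sigma == 0:
        p = np.where(gaps > 0, 1.0, np.where(gaps < 0, 0.0, 0.5))
    else:
        p = norm.cdf(gaps / (sigma * np.sqrt(2.0)))
    return float(np.mean(np.maximum(p, 1.0 - p)))


def write_study(
    study: ExpressionStudy,
    collection: NetworkCollection,
    truth: StudyTruth,
    out_dir: str | Path,
    stem: str = "synthetic",
) -> dict[str, Path]:
    """Write GCT + CLS + GMT (+ truth TSV) so downstream readers are exercised."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gct": out_dir / f"{stem}.gct",
        "cls": out_dir / f"{stem}.cls",
        "gmt": out_dir / f"{stem}.gmt",
        "truth": out_dir / f"{stem}_truth.tsv",
    }
    write_expression_gct(study, paths["gct"])
    write_cls(list(study.labels), paths["cls"])
    write_gmt(collection, paths["gmt"])
    write_table(truth.to_frame(), paths["truth"])
    return paths
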