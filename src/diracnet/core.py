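"""The DIRAC statistics.

A network of G genes induces P = G(G-1)/2 ordered gene pairs.  Each sample
is encoded as the binary vector of its pairwise orderings; a phenotype's
rank template is the majority vote over its samples' encodings.  Everything
else — the rank matching score R, the rank conservation index mu_R, the
rank difference score Delta, the classification rate eta, and the
normalised template Hamming distance — is counting agreements between
binary vectors, so all statistics are invariant to any strictly increasing
transform applied per sample and depend only on the genes inside the
network.

Scores are computed as exact integer agreement counts divided once at the
end, so there is no floating-point accumulation error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionStudy, GeneNetwork

__all__ = [
    "enumerate_pairs",
    "encode_sample",
    "encode_network",
    "RankTemplate",
    "estimate_template",
    "matching_score",
    "conservation_index",
    "difference_score",
    "template_difference",
    "classification_rate",
    "conservation_table",
    "score_networks",
    "NetworkScores",
]


def enumerate_pairs(n_genes: int) -> np.ndarray:
    """All index pairs (i, j) with i < j, lexicographic, shape (P, 2).

    For ``n_genes`` = 4 the six pairs are (0,1),(0,2),(0,3),(1,2),(1,3),(2,3).
    """
    if n_genes < 2:
        raise ValueError(f"need at least 2 genes, got {n_genes}")
    i, j = np.triu_indices(n_genes, k=1)
    return np.column_stack([i, j])


def _as_bits(template: "RankTemplate | np.ndarray | Sequence[int]") -> np.ndarray:
    if isinstance(template, RankTemplate):
        return template.bits
    return np.asarray(template, dtype=np.uint8)


def encode_sample(profile: Sequence[float], pairs: np.ndarray | None = None) -> np.ndarray:
    """Binary pair encoding of one expression profile.

    Entry for pair (i, j) is 1 iff ``profile[i] < profile[j]`` strictly;
    ties score 0 ("not less"), the same rule used in template estimation.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")
    if pairs is None:
        pairs = enumerate_pairs(len(x))
    return (x[pairs[:, 0]] < x[pairs[:, 1]]).astype(np.uint8)


def encode_network(values: np.ndarray, pairs: np.ndarray | None = None) -> np.ndarray:
    """Encode every sample of a (genes x samples) block; shape (N, P)."""
    vals = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("expression block contains non-finite values")
    if pairs is None:
        pairs = enumerate_pairs(vals.shape[0])
    return (vals[pairs[:, 0], :] < vals[pairs[:, 1], :]).T.astype(np.uint8)


@dataclass(frozen=True)
class RankTemplate:
    """Majority pairwise-ordering template for one (network, phenotype).

    ``probs[p]`` estimates Pr(X_i < X_j | phenotype) for pair p as the
    fraction of that phenotype's samples expressing gene i below gene j;
    ``bits[p]`` is 1 iff ``probs[p] > 0.5`` (exactly 0.5 gives 0).
    """

    network: str
    phenotype: str
    probs: np.ndarray
    bits: np.ndarray
    n_samples: int

    def __len__(self) -> int:
        return len(self.bits)


def estimate_template(
    encodings: np.ndarray,
    network: str = "",
    phenotype: str = "",
) -> RankTemplate:
    """Estimate the rank template from an (N, P) array of pair encodings."""
    enc = np.asarray(encodings)
    if enc.ndim != 2 or enc.shape[0] == 0:
        raise ValueError("need a non-empty (samples x pairs) encoding array")
    if enc.shape[0] == 1:
        import warnings

        warnings.warn(
            "estimating a rank template from a single sample",
            stacklevel=2,
        )
    probs = enc.mean(axis=0)
    bits = (probs > 0.5).astype(np.uint8)
    return RankTemplate(
        network=network,
        phenotype=phenotype,
        probs=probs,
        bits=bits,
        n_samples=enc.shape[0],
    )


def matching_score(encoding: np.ndarray, template) -> float:
    """Fraction of pairs on which a sample's ordering matches the template."""
    enc = np.asarray(encoding, dtype=np.uint8)
    bits = _as_bits(template)
    if enc.shape != bits.shape:
        raise ValueError(f"length mismatch: {enc.shape} vs {bits.shape}")
    return int(np.sum(enc == bits)) / len(bits)


def conservation_index(encodings: np.ndarray, template) -> float:
    """Rank conservation index mu_R: mean matching score over samples.

    Near 1 the phenotype's samples share one ordering (tight regulation);
    near 0.5 orderings shuffle freely from sample to sample.
    """
    enc = np.asarray(encodings, dtype=np.uint8)
    if enc.ndim != 2 or enc.shape[0] == 0:
        raise ValueError("need a non-empty (samples x pairs) encoding array")
    bits = _as_bits(template)
    if enc.shape[1] != len(bits):
        raise ValueError(f"length mismatch: {enc.shape[1]} vs {len(bits)}")
    agree = int(np.sum(enc == bits[None, :]))
    return agree / (enc.shape[0] * len(bits))


def difference_score(encoding: np.ndarray, template_a, template_b) -> float:
    """Rank difference score Delta = R(template A) - R(template B).

    Lies in [-1, 1]; positive values are evidence for phenotype A.  Pairs on
    which the two templates agree cancel, so Delta reduces to signed voting
    over the straddling pairs (those whose class probabilities sit on
    opposite sides of 0.5), divided by the total pair count.
    """
    enc = np.asarray(encoding, dtype=np.uint8)
    bits_a, bits_b = _as_bits(template_a), _as_bits(template_b)
    if not (enc.shape == bits_a.shape == bits_b.shape):
        raise ValueError("encoding and templates must have equal length")
    agree_a = int(np.sum(enc == bits_a))
    agree_b = int(np.sum(enc == bits_b))
    return (agree_a - agree_b) / len(enc)


def template_difference(template_a, template_b) -> float:
    """Normalised Hamming distance between two templates, in [0, 1].

    Only these differing ("straddling") pairs contribute to Delta; the
    unnormalised count is the k of the induced k-pair voting classifier.
    """
    bits_a, bits_b = _as_bits(template_a), _as_bits(template_b)
    if bits_a.shape != bits_b.shape:
        raise ValueError("templates must have equal length")
    return int(np.sum(bits_a != bits_b)) / len(bits_a)


def classification_rate(
    deltas: Sequence[float],
    labels: Sequence[str],
    phenotype_a: str,
    phenotype_b: str,
) -> float:
    """Balanced accuracy eta of the sign-of-Delta rule.

    A sample is called phenotype A iff Delta > 0 (Delta = 0 goes to B);
    eta is the average of sensitivity (A-samples with Delta > 0) and
    specificity (B-samples with Delta <= 0).
    """
    d = np.asarray(deltas, dtype=float)
    y = np.asarray(labels)
    if d.shape != y.shape:
        raise ValueError("one delta per sample required")
    mask_a = y == phenotype_a
    mask_b = y == phenotype_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError(
            f"both phenotypes must be present (got {sorted(set(y))})"
        )
    sensitivity = float(np.mean(d[mask_a] > 0))
    specificity = float(np.mean(d[mask_b] <= 0))
    return (sensitivity + specificity) / 2


# ---------------------------------------------------------------------------
# Study-level tables


def _network_block(study: ExpressionStudy, network: GeneNetwork) -> np.ndarray:
    missing = [g for g in network.genes if g not in study.values.index]
    if missing:
        raise KeyError(
            f"network {network.name!r}: genes missing from study: {missing}"
        )
    return study.values.loc[list(network.genes)].to_numpy()


def network_encodings(study: ExpressionStudy, network: GeneNetwork) -> np.ndarray:
    """Pair encodings (N, P) of every study sample for one network."""
    return encode_network(_network_block(study, network))


def conservation_table(
    study: ExpressionStudy,
    networks: Sequence[GeneNetwork],
    phenotypes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """mu_R for every (network, phenotype): networks x phenotypes DataFrame.

    Each phenotype's template is estimated from its own samples and scored
    on those same samples.
    """
    if study.labels is None:
        raise ValueError("study has no phenotype labels")
    if phenotypes is None:
        phenotypes = study.phenotypes
    study.require_min_class_size(2)
    label_arr = study.labels.to_numpy()
    rows = {}
    for net in networks:
        enc = network_encodings(study, net)
        rows[net.name] = {}
        for k in phenotypes:
            enc_k = enc[label_arr == k]
            tpl = estimate_template(enc_k, net.name, k)
            rows[net.name][k] = conservation_index(enc_k, tpl)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.loc[[n.name for n in networks], list(phenotypes)]
    table.index.name = "network"
    return table


@dataclass
class NetworkScores:
    """Per-network and per-sample DIRAC statistics for one phenotype pair.

    ``networks`` columns: mu_R for each phenotype, theta (absolute mu_R
    difference), eta (apparent classification rate of the sign-of-Delta
    rule), template_distance.  ``samples`` columns (one frame per network
    name): R against each template and Delta.
    """

    phenotype_a: str
    phenotype_b: str
    networks: pd.DataFrame
    samples: dict[str, pd.DataFrame]
    templates: dict[str, tuple[RankTemplate, RankTemplate]]


def score_networks(
    study: ExpressionStudy,
    networks: Sequence[GeneNetwork],
    phenotypes: tuple[str, str],
) -> NetworkScores:
    """Full two-phenotype score table: mu_R, theta, Delta, eta per network."""
    if study.labels is None:
        raise ValueError("study has no phenotype labels")
    a, b = phenotypes
    label_arr = study.labels.to_numpy()
    mask_a, mask_b = label_arr == a, label_arr == b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per phenotype ({a}: {mask_a.sum()}, "
            f"{b}: {mask_b.sum()})"
        )
    net_rows = []
    per_sample: dict[str, pd.DataFrame] = {}
    templates: dict[str, tuple[RankTemplate, RankTemplate]] = {}
    for net in networks:
        enc = network_encodings(study, net)
        tpl_a = estimate_template(enc[mask_a], net.name, a)
        tpl_b = estimate_template(enc[mask_b], net.name, b)
        p = enc.shape[1]
        agree_a = (enc == tpl_a.bits[None, :]).sum(axis=1)
        agree_b = (enc == tpl_b.bits[None, :]).sum(axis=1)
        r_a, r_b = agree_a / p, agree_b / p
        delta = (agree_a - agree_b) / p
        mu_a = float(r_a[mask_a].mean())
        mu_b = float(r_b[mask_b].mean())
        eta = classification_rate(delta, label_arr, a, b)
        net_rows.append(
            {
                "network": net.name,
                "n_genes": net.size,
                "n_pairs": p,
                f"mu_{a}": mu_a,
                f"mu_{b}": mu_b,
                "theta": abs(mu_a - mu_b),
                "eta": eta,
                "template_distance": template_difference(tpl_a, tpl_b),
            }
        )
        per_sample[net.name] = pd.DataFrame(
            {
                "sample": study.sample_ids,
                "phenotype": label_arr,
                f"R_{a}": r_a,
                f"R_{b}": r_b,
                "delta": delta,
            }
        )
        templates[net.name] = (tpl_a, tpl_b)
    frame = pd.DataFrame(net_rows).set_index("network")
    return NetworkScores(
        phenotype_a=a,
        phenotype_b=b,
        networks=frame,
        samples=per_sample,
        templates=templates,
    )


def templates_to_frame(
    template_a: RankTemplate, template_b: RankTemplate, genes: Sequence[str]
) -> pd.DataFrame:
    """Human-readable TSV-ready view of a template pair over named genes."""
    pairs = enumerate_pairs(len(genes))
    return pd.DataFrame(
        {
            "gene_i": [genes[i] for i in pairs[:, 0]],
            "gene_j": [genes[j] for j in pairs[:, 1]],
            f"prob_{template_a.phenotype}": template_a.probs,
            f"bit_{template_a.phenotype}": template_a.bits,
            f"prob_{template_b.phenotype}": template_b.probs,
            f"bit_{template_b.phenotype}": template_b.bits,
        }
    )
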