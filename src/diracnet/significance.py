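"""Population-level inference for DIRAC statistics.

Two permutation tests share one engine: phenotype labels are shuffled
(class sizes preserved), templates are re-estimated within each permuted
labelling, and the statistic — theta(m) = |mu_R difference| for network
deregulation, eta(m) for the sign-of-Delta classification rate — is
recomputed.  P-values use add-one smoothing, p = (1 + #{null >= observed})
/ (B + 1), so they are never zero.  The permutation FDR is the plug-in
estimator: expected null exceedance count over observed exceedance count,
capped at 1 and made monotone from the largest statistic down.

The engine is pure integer linear algebra: with the (N, P) pair-encoding
matrix E of a network and a (B, N) 0/1 class-membership matrix Z, the class
pair probabilities for all permutations are Z @ E row-scaled, and agreement
counts between samples and permuted templates come from one more matrix
product — no per-permutation Python loop over samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import network_encodings
from .io import ExpressionStudy, GeneNetwork

__all__ = [
    "SignificanceReport",
    "deregulation_test",
    "classification_test",
    "exhaustive_null",
    "permutation_fdr",
    "binomial_deregulation_pvalue",
    "count_deregulated",
    "global_conservation",
]


@dataclass
class SignificanceReport:
    """Observed statistics, permutation p-values and FDR per network.

    ``table`` columns: the observed statistic, per-phenotype mu_R,
    ``p_value`` and ``fdr``; ``null`` holds the (B, networks) permutation
    null draws for reuse (e.g. exhaustive cross-checks).
    """

    statistic: str
    phenotype_a: str
    phenotype_b: str
    n_permutations: int
    seed: int | None
    table: pd.DataFrame
    null: np.ndarray


def _class_masks(labels: np.ndarray, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    mask_a, mask_b = labels == a, labels == b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per phenotype ({a}: {mask_a.sum()}, "
            f"{b}: {mask_b.sum()})"
        )
    return mask_a, mask_b


def _membership_matrix(
    n_samples: int,
    n_a: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(B, N) 0/1 matrix; each row marks a random size-n_a subset as class A."""
    z = np.zeros((n_permutations, n_samples), dtype=np.float64)
    for b in range(n_permutations):
        idx = rng.choice(n_samples, size=n_a, replace=False)
        z[b, idx] = 1.0
    return z


def _permuted_stats(
    enc: np.ndarray,
    z_a: np.ndarray,
    statistic: str,
) -> np.ndarray:
    """theta or eta for one network under every permuted labelling.

    ``enc`` is (N, P) in {0,1}; ``z_a`` is (B, N) with exactly n_a ones per
    row (class A membership).  Agreement counts between sample encodings
    and the permuted majority templates are expanded as
    sum_p [e == t] = 2 e.t - sum(e) - sum(t) + P.
    """
    n, p = enc.shape
    n_a = int(z_a[0].sum())
    n_b = n - n_a
    e = enc.astype(np.float64)
    z_b = 1.0 - z_a
    counts_a = z_a @ e                       # (B, P) class-A "less" counts
    counts_b = z_b @ e
    bits_a = (counts_a > n_a / 2).astype(np.float64)
    bits_b = (counts_b > n_b / 2).astype(np.float64)
    row_e = e.sum(axis=1)                    # (N,)
    # agreement counts, (N, B)
    agree_a = 2.0 * (e @ bits_a.T) - row_e[:, None] - bits_a.sum(axis=1)[None, :] + p
    agree_b = 2.0 * (e @ bits_b.T) - row_e[:, None] - bits_b.sum(axis=1)[None, :] + p
    if statistic == "theta":
        mu_a = np.einsum("bn,nb->b", z_a, agree_a) / (n_a * p)
        mu_b = np.einsum("bn,nb->b", z_b, agree_b) / (n_b * p)
        return np.abs(mu_a - mu_b)
    if statistic == "eta":
        pred_a = (agree_a > agree_b)         # Delta > 0, (N, B)
        sens = np.einsum("bn,nb->b", z_a, pred_a) / n_a
        spec = np.einsum("bn,nb->b", z_b, ~pred_a) / n_b
        return (sens + spec) / 2.0
    raise ValueError(f"unknown statistic {statistic!r}")


def _observed_stats(
    enc: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> tuple[float, float, float, float]:
    """(mu_a, mu_b, theta, eta) for the observed labelling of one network."""
    z = np.zeros((1, enc.shape[0]))
    z[0, mask_a] = 1.0
    theta = float(_permuted_stats(enc, z, "theta")[0])
    eta = float(_permuted_stats(enc, z, "eta")[0])
    # mu values recomputed directly for the report
    n_a, n_b, p = mask_a.sum(), mask_b.sum(), enc.shape[1]
    bits_a = (enc[mask_a].sum(axis=0) > n_a / 2)
    bits_b = (enc[mask_b].sum(axis=0) > n_b / 2)
    mu_a = float((enc[mask_a] == bits_a[None, :]).mean())
    mu_b = float((enc[mask_b] == bits_b[None, :]).mean())
    return mu_a, mu_b, theta, eta


def _permutation_test(
    study: ExpressionStudy,
    networks: Sequence[GeneNetwork],
    phenotypes: tuple[str, str],
    statistic: str,
    n_permutations: int,
    seed: int | None,
) -> SignificanceReport:
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if study.labels is None:
        raise ValueError("study has no phenotype labels")
    a, b = phenotypes
    labels = study.labels.to_numpy()
    mask_a, mask_b = _class_masks(labels, a, b)
    keep = mask_a | mask_b
    rng = np.random.default_rng(seed)
    z_a = _membership_matrix(int(keep.sum()), int(mask_a.sum()), n_permutations, rng)

    names, observed, null_cols, rows = [], [], [], []
    sub_mask_a = mask_a[keep]
    sub_mask_b = mask_b[keep]
    sample_index = np.flatnonzero(keep)
    for net in networks:
        enc = network_encodings(study, net)[sample_index]
        mu_a, mu_b, theta, eta = _observed_stats(enc, sub_mask_a, sub_mask_b)
        obs = theta if statistic == "theta" else eta
        null = _permuted_stats(enc, z_a, statistic)
        names.append(net.name)
        observed.append(obs)
        null_cols.append(null)
        rows.append({"network": net.name, f"mu_{a}": mu_a, f"mu_{b}": mu_b,
                     "theta": theta, "eta": eta, statistic: obs})
    null_matrix = np.column_stack(null_cols)          # (B, M)
    observed_arr = np.asarray(observed)
    exceed = (null_matrix >= observed_arr[None, :]).sum(axis=0)
    p_values = (1 + exceed) / (n_permutations + 1)
    fdr = permutation_fdr(observed_arr, null_matrix)
    table = pd.DataFrame(rows).set_index("network")
    table["p_value"] = p_values
    table["fdr"] = fdr
    return SignificanceReport(
        statistic=statistic,
        phenotype_a=a,
        phenotype_b=b,
        n_permutations=n_permutations,
        seed=seed,
        table=table,
        null=null_matrix,
    )


def deregulation_test(
    study: ExpressionStudy,
    networks: Sequence[GeneNetwork],
    phenotypes: tuple[str, str],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> SignificanceReport:
    """Permutation test for network deregulation.

    The statistic is theta(m) = |mu_R(m, A) - mu_R(m, B)|; under the null
    the labels are shuffled and both templates re-estimated within each
    permuted labelling.
    """
    return _permutation_test(
        study, networks, phenotypes, "theta", n_permutations, seed
    )


def classification_test(
    study: ExpressionStudy,
    networks: Sequence[GeneNetwork],
    phenotypes: tuple[str, str],
    n_permutations: int = 10000,
    seed: int | None = None,
) -> SignificanceReport:
    """Permutation test for the network classification rate eta(m).

    Per permutation, templates and per-sample Delta are recomputed and
    samples predicted A iff Delta > 0; eta is the average of sensitivity
    and specificity under the permuted labels.
    """
    return _permutation_test(
        study, networks, phenotypes, "eta", n_permutations, seed
    )


def exhaustive_null(
    study: ExpressionStudy,
    network: GeneNetwork,
    phenotypes: tuple[str, str],
    statistic: str = "theta",
) -> tuple[float, np.ndarray]:
    """Observed statistic and its complete label-assignment null.

    Enumerates every way of assigning n_A of the samples to phenotype A
    (C(N, n_A) assignments) — feasible only for small N; serves as the
    exact oracle against which the Monte-Carlo test is checked.
    """
    labels = study.labels.to_numpy()
    a, b = phenotypes
    mask_a, mask_b = _class_masks(labels, a, b)
    keep = mask_a | mask_b
    enc = network_encodings(study, network)[np.flatnonzero(keep)]
    n = int(keep.sum())
    n_a = int(mask_a.sum())
    combos = list(itertools.combinations(range(n), n_a))
    z = np.zeros((len(combos), n))
    for row, idx in enumerate(combos):
        z[row, list(idx)] = 1.0
    null = _permuted_stats(enc, z, statistic)
    mu_a, mu_b, theta, eta = _observed_stats(enc, mask_a[keep], mask_b[keep])
    obs = theta if statistic == "theta" else eta
    return obs, null


def permutation_fdr(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Plug-in permutation FDR evaluated at each observed statistic.

    The raw estimate at threshold c is [mean over permutations of
    #{null >= c}] / max(1, #{observed >= c}), capped at 1.  It is then made
    monotone non-increasing in the statistic q-value style: each observed
    value receives the minimum raw estimate over all thresholds at or below
    it (every such rejection region contains the observation), so a larger
    statistic never reports a larger FDR.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if null.ndim != 2 or null.shape[1] != observed.shape[0]:
        raise ValueError(
            f"null matrix shape {null.shape} does not match "
            f"{observed.shape[0]} observed statistics"
        )
    n_perm = null.shape[0]
    flat_null = np.sort(null.ravel())
    fdr = np.empty_like(observed)
    running_min = np.inf
    for idx in np.argsort(observed, kind="stable"):  # smallest threshold first
        c = observed[idx]
        mean_null_exceed = (
            flat_null.size - np.searchsorted(flat_null, c, side="left")
        ) / n_perm
        n_observed_exceed = int((observed >= c).sum())
        raw = min(1.0, mean_null_exceed / max(1, n_observed_exceed))
        running_min = min(running_min, raw)
        fdr[idx] = running_min
    return fdr


def binomial_deregulation_pvalue(
    k_less: int, k_more: int, tail: str = "strict"
) -> float:
    """Sign-test p-value for an excess of networks tighter in one phenotype.

    Of the significantly deregulated networks, ``k_less`` were more tightly
    regulated (higher mu_R) in the less-malignant phenotype and ``k_more``
    in the more-malignant one.  Under the null each network falls either
    way with probability 1/2.  ``tail='strict'`` returns the upper tail
    strictly above k_less, Pr(X > k_less) with X ~ Binomial(k_less +
    k_more, 0.5); ``tail='inclusive'`` returns the conventional
    Pr(X >= k_less).
    """
    if k_less < 0 or k_more < 0:
        raise ValueError("counts must be non-negative")
    n = k_less + k_more
    if n < 1:
        raise ValueError("need at least one deregulated network")
    if tail == "strict":
        return float(stats.binom.sf(k_less, n, 0.5))
    if tail == "inclusive":
        return float(stats.binom.sf(k_less - 1, n, 0.5))
    raise ValueError(f"unknown tail convention {tail!r}")


def count_deregulated(
    report: SignificanceReport,
    less_malignant: str,
    more_malignant: str,
    alpha: float = 0.05,
) -> tuple[int, int]:
    """Split significantly deregulated networks by which phenotype is tighter.

    Among networks with p < alpha in a deregulation report, counts those
    with higher mu_R in the less-malignant phenotype versus higher in the
    more-malignant one; exact mu_R ties are excluded (and logged).
    """
    cols = {report.phenotype_a, report.phenotype_b}
    if {less_malignant, more_malignant} != cols:
        raise ValueError(
            f"phenotypes ({less_malignant}, {more_malignant}) do not match "
            f"report ({report.phenotype_a}, {report.phenotype_b})"
        )
    tab = report.table
    sig = tab[tab["p_value"] < alpha]
    mu_less = sig[f"mu_{less_malignant}"]
    mu_more = sig[f"mu_{more_malignant}"]
    k_less = int((mu_less > mu_more).sum())
    k_more = int((mu_more > mu_less).sum())
    n_tied = len(sig) - k_less - k_more
    if n_tied:
        import logging

        logging.getLogger(__name__).info(
            "excluding %d significant networks with exactly tied mu_R", n_tied
        )
    return k_less, k_more


def global_conservation(
    mu_table: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Global regulation summary: per-phenotype mean mu_R and ANOVA p-value.

    ``mu_table`` is networks x phenotypes.  Returns the phenotype means
    sorted descending (most tightly regulated first) and the one-way ANOVA
    p-value across phenotype groups, treating networks as independent
    observations within each group.
    """
    if mu_table.shape[0] < 2 or mu_table.shape[1] < 2:
        raise ValueError("need >= 2 networks and >= 2 phenotypes")
    means = mu_table.mean(axis=0).sort_values(ascending=False)
    groups = [mu_table[c].to_numpy() for c in mu_table.columns]
    if all(np.allclose(g, groups[0]) for g in groups[1:]):
        return means, 1.0
    _, p_value = stats.f_oneway(*groups)
    return means, float(p_value)
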