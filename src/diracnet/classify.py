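"""Sample-level classification by rank templates.

The DIRAC classifier picks, on training data, the network with the largest
apparent classification rate eta (average of sensitivity and specificity of
the sign-of-Delta rule) and calls a new sample phenotype A iff its rank
difference score for that network is positive.  Generalisation is measured
by leave-one-out cross-validation in which every training decision —
template estimation, network selection, gene filtering, pair search — is
repeated inside each split, so no information from the held-out sample
leaks into training.

Two comparators mirror the standard alternatives: the top-scoring-pair
(TSP) classifier on Wilcoxon-filtered genes, and a Gaussian-kernel SVM on
the same filtered genes.  Both filter to as many genes as the best
DIRAC-selected network contains, making the comparison size-matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import RankTemplate, encode_sample, score_networks
from .io import ExpressionStudy, GeneNetwork

__all__ = [
    "DiracModel",
    "TspModel",
    "train_dirac",
    "predict_dirac",
    "wilcoxon_top_genes",
    "train_tsp",
    "predict_tsp",
    "loocv",
    "LoocvResult",
]


@dataclass
class DiracModel:
    """A trained single-network DIRAC classifier."""

    phenotype_a: str
    phenotype_b: str
    network: GeneNetwork
    template_a: RankTemplate
    template_b: RankTemplate
    apparent_eta: float
    tie_trace: list[str]


@dataclass
class TspModel:
    """A trained top-scoring-pair classifier.

    ``prob_a``/``prob_b`` are the training estimates of Pr(X_i < X_j) in
    each class; the score is their absolute difference.  A sample votes for
    the class whose training probability better matches its observed
    ordering of the two genes.
    """

    phenotype_a: str
    phenotype_b: str
    gene_i: str
    gene_j: str
    prob_a: float
    prob_b: float
    score: float
    candidate_genes: list[str]


def train_dirac(
    study: ExpressionStudy,
    networks: Sequence[GeneNetwork],
    phenotypes: tuple[str, str],
) -> DiracModel:
    """Select the most variably expressed network on training data.

    eta is computed per network on the training samples; the network with
    maximal eta wins.  Ties break deterministically: larger template
    Hamming distance, then lexicographically smaller name.
    """
    if not networks:
        raise ValueError("no networks to train on")
    scores = score_networks(study, list(networks), phenotypes)
    tab = scores.networks
    best_eta = tab["eta"].max()
    tied = tab[tab["eta"] == best_eta]
    trace = []
    if len(tied) > 1:
        trace.append(
            f"eta tie among {sorted(tied.index)} at {best_eta:.4g}"
        )
        best_dist = tied["template_distance"].max()
        tied = tied[tied["template_distance"] == best_dist]
        if len(tied) > 1:
            trace.append(
                f"template-distance tie among {sorted(tied.index)}"
            )
    winner = sorted(tied.index)[0]
    net = next(n for n in networks if n.name == winner)
    tpl_a, tpl_b = scores.templates[winner]
    return DiracModel(
        phenotype_a=phenotypes[0],
        phenotype_b=phenotypes[1],
        network=net,
        template_a=tpl_a,
        template_b=tpl_b,
        apparent_eta=float(best_eta),
        tie_trace=trace,
    )


def predict_dirac(model: DiracModel, sample: pd.Series) -> str:
    """Classify one sample (Series indexed by gene) by the sign of Delta."""
    missing = [g for g in model.network.genes if g not in sample.index]
    if missing:
        raise KeyError(
            f"sample lacks genes of network {model.network.name!r}: {missing}"
        )
    profile = sample.loc[list(model.network.genes)].to_numpy(dtype=float)
    enc = encode_sample(profile)
    agree_a = int(np.sum(enc == model.template_a.bits))
    agree_b = int(np.sum(enc == model.template_b.bits))
    return model.phenotype_a if agree_a > agree_b else model.phenotype_b


def wilcoxon_top_genes(
    study: ExpressionStudy,
    phenotypes: tuple[str, str],
    n_genes: int,
) -> list[str]:
    """Rank genes by two-sided Wilcoxon rank-sum p-value, return the top G.

    Uses exact enumeration for small groups (both class sizes <= 20) and
    the tie-corrected normal approximation otherwise.  Ties in p-value are
    broken by the larger deviation of the rank-sum statistic from its null
    mean, then by gene name.
    """
    if study.labels is None:
        raise ValueError("study has no phenotype labels")
    if n_genes > len(study.gene_ids):
        raise ValueError(
            f"requested {n_genes} genes but study has {len(study.gene_ids)}"
        )
    a, b = phenotypes
    labels = study.labels.to_numpy()
    mask_a, mask_b = labels == a, labels == b
    vals = study.values.to_numpy()
    x_a, x_b = vals[:, mask_a], vals[:, mask_b]
    n_a, n_b = mask_a.sum(), mask_b.sum()
    method = "exact" if max(n_a, n_b) <= 20 else "asymptotic"
    rows = []
    null_mean_u = n_a * n_b / 2.0
    for g, gene in enumerate(study.gene_ids):
        res = stats.mannwhitneyu(
            x_a[g], x_b[g], alternative="two-sided", method=method
        )
        rows.append(
            (float(res.pvalue), -abs(float(res.statistic) - null_mean_u), gene)
        )
    rows.sort()
    return [gene for _, _, gene in rows[:n_genes]]


def _rank_margin(
    vals: np.ndarray, gi: int, gj: int, mask_a: np.ndarray, mask_b: np.ndarray
) -> float:
    """Secondary TSP score: between-class gap in mean within-sample rank gap."""
    ranks = stats.rankdata(vals, axis=0)
    diff = ranks[gi] - ranks[gj]
    return abs(float(diff[mask_a].mean()) - float(diff[mask_b].mean()))


def train_tsp(
    study: ExpressionStudy,
    phenotypes: tuple[str, str],
) -> TspModel:
    """Exhaustive search for the pair maximising |Pr(X_i<X_j|A) - Pr(..|B)|.

    ``study`` should already be restricted to the candidate (filtered)
    genes.  Score ties break by the larger between-class rank-difference
    margin, then by the lexicographically smaller gene pair.
    """
    if study.labels is None:
        raise ValueError("study has no phenotype labels")
    genes = study.gene_ids
    if len(genes) < 2:
        raise ValueError("need >= 2 candidate genes for a pair search")
    a, b = phenotypes
    labels = study.labels.to_numpy()
    mask_a, mask_b = labels == a, labels == b
    vals = study.values.to_numpy()
    less = vals[:, None, :] < vals[None, :, :]     # (G, G, N): X_i < X_j
    p_a = less[:, :, mask_a].mean(axis=2)
    p_b = less[:, :, mask_b].mean(axis=2)
    score = np.abs(p_a - p_b)
    iu = np.triu_indices(len(genes), k=1)
    best_score = score[iu].max()
    candidates = [
        (int(i), int(j))
        for i, j in zip(*iu)
        if score[i, j] == best_score
    ]
    if len(candidates) > 1:
        keyed = sorted(
            candidates,
            key=lambda ij: (
                -_rank_margin(vals, ij[0], ij[1], mask_a, mask_b),
                genes[ij[0]],
                genes[ij[1]],
            ),
        )
        gi, gj = keyed[0]
    else:
        gi, gj = candidates[0]
    return TspModel(
        phenotype_a=a,
        phenotype_b=b,
        gene_i=genes[gi],
        gene_j=genes[gj],
        prob_a=float(p_a[gi, gj]),
        prob_b=float(p_b[gi, gj]),
        score=float(best_score),
        candidate_genes=list(genes),
    )


def predict_tsp(model: TspModel, sample: pd.Series) -> str:
    """Classify by the learned orientation of the selected gene pair."""
    for gene in (model.gene_i, model.gene_j):
        if gene not in sample.index:
            raise KeyError(f"sample lacks gene {gene!r}")
    observed_less = float(sample[model.gene_i]) < float(sample[model.gene_j])
    p_obs_a = model.prob_a if observed_less else 1.0 - model.prob_a
    p_obs_b = model.prob_b if observed_less else 1.0 - model.prob_b
    return model.phenotype_a if p_obs_a > p_obs_b else model.phenotype_b


def _train_predict_svm(
    train: ExpressionStudy,
    test_sample: pd.Series,
    phenotypes: tuple[str, str],
    n_genes: int,
) -> str:
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    genes = wilcoxon_top_genes(train, phenotypes, n_genes)
    x_train = train.values.loc[genes].to_numpy().T
    scaler = StandardScaler().fit(x_train)
    clf = SVC(kernel="rbf").fit(scaler.transform(x_train), train.labels.to_numpy())
    x_test = test_sample.loc[genes].to_numpy(dtype=float)[None, :]
    return str(clf.predict(scaler.transform(x_test))[0])


@dataclass
class LoocvResult:
    """Held-out predictions and the cross-validated classification rate."""

    method: str
    phenotype_a: str
    phenotype_b: str
    rate: float
    predictions: pd.DataFrame   # sample, true, predicted, selected network/pair


def loocv(
    study: ExpressionStudy,
    networks: Sequence[GeneNetwork],
    phenotypes: tuple[str, str],
    method: str = "dirac",
    seed: int | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation of a classifier.

    Runs N train/test splits; within each, the complete training procedure
    reruns on the N-1 remaining samples.  Held-out predictions are pooled
    first and sensitivity/specificity computed once over all N of them,
    then averaged into the cross-validated rate.  ``seed`` feeds the SVM
    comparator (the rank methods are deterministic).
    """
    if method not in {"dirac", "tsp", "svm"}:
        raise ValueError(f"unknown method {method!r}")
    if study.labels is None:
        raise ValueError("study has no phenotype labels")
    a, b = phenotypes
    keep = study.labels.isin([a, b])
    study = study.subset_samples(study.labels.index[keep])
    n = study.n_samples
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    counts = study.labels.value_counts()
    if counts.get(a, 0) < 2 or counts.get(b, 0) < 2:
        raise ValueError("need >= 2 samples per phenotype")
    rows = []
    for held_out in study.sample_ids:
        train_ids = [s for s in study.sample_ids if s != held_out]
        train = study.subset_samples(train_ids)
        train_counts = train.labels.value_counts()
        if train_counts.get(a, 0) < 1 or train_counts.get(b, 0) < 1:
            raise ValueError(
                f"split holding out {held_out!r} loses a phenotype entirely"
            )
        test_sample = study.values[held_out]
        dirac_model = train_dirac(train, networks, phenotypes)
        if method == "dirac":
            predicted = predict_dirac(dirac_model, test_sample)
            detail = dirac_model.network.name
        elif method == "tsp":
            genes = wilcoxon_top_genes(
                train, phenotypes, dirac_model.network.size
            )
            filtered = ExpressionStudy(train.values.loc[genes], train.labels)
            tsp = train_tsp(filtered, phenotypes)
            predicted = predict_tsp(tsp, test_sample)
            detail = f"{tsp.gene_i}<{tsp.gene_j}"
        else:
            predicted = _train_predict_svm(
                train, test_sample, phenotypes, dirac_model.network.size
            )
            detail = f"svm:{dirac_model.network.size}genes"
        rows.append(
            {
                "sample": held_out,
                "true": study.labels[held_out],
                "predicted": predicted,
                "detail": detail,
            }
        )
    preds = pd.DataFrame(rows)
    sens = float((preds.loc[preds["true"] == a, "predicted"] == a).mean())
    spec = float((preds.loc[preds["true"] == b, "predicted"] == b).mean())
    return LoocvResult(
        method=method,
        phenotype_a=a,
        phenotype_b=b,
        rate=(sens + spec) / 2,
        predictions=preds,
    )
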