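"""Tests for the rank-template classifiers and cross-validation protocol."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_study
from diracnet import (
    ExpressionStudy,
    classification_rate,
    loocv,
    predict_dirac,
    predict_tsp,
    score_networks,
    train_dirac,
    train_tsp,
    wilcoxon_top_genes,
)
from diracnet.io import GeneNetwork
from diracnet.synth import SynthSpec, generate_study


class TestTrainDirac:
    def test_planted_network_selected_in_nearly_all_replicates(self):
        """One network carries a 20-pair template reversal, the rest are
        noise: that network should win training selection almost always."""
        hits = 0
        reps = 100
        for rep in range(reps):
            spec = SynthSpec(
                n_networks=8, n_discriminative=1, n_samples_a=15,
                n_samples_b=15, seed=3000 + rep,
            )
            study, nets, truth = generate_study(spec)
            model = train_dirac(study, list(nets), ("A", "B"))
            hits += model.network.name == truth.discriminative[0]
        assert hits >= 95

    def test_selected_eta_matches_recomputed_classification_rate(
        self, planted_study
    ):
        study, nets, _ = planted_study
        model = train_dirac(study, nets, ("A", "B"))
        scores = score_networks(study, [model.network], ("A", "B"))
        deltas = scores.samples[model.network.name]["delta"]
        eta = classification_rate(
            deltas, study.labels.to_numpy(), "A", "B"
        )
        assert model.apparent_eta == pytest.approx(eta)
        assert model.apparent_eta == pytest.approx(
            scores.networks["eta"].max()
        )

    def test_tie_breaks_by_template_distance_then_name(self):
        """Identical matrices in two networks tie on eta; the deterministic
        winner is the larger template distance, then the smaller name."""
        rng = np.random.default_rng(4)
        block = rng.normal(size=(4, 12))
        values = np.vstack([block, block])  # two identical networks
        study = make_study(values, labels=["A"] * 6 + ["B"] * 6)
        nets = [
            GeneNetwork("ZNET", ("G00", "G01", "G02", "G03")),
            GeneNetwork("ANET", ("G04", "G05", "G06", "G07")),
        ]
        model = train_dirac(study, nets, ("A", "B"))
        assert model.network.name == "ANET"
        assert model.tie_trace  # the tie was recorded

    def test_no_networks_rejected(self, planted_study):
        study, _, _ = planted_study
        with pytest.raises(ValueError):
            train_dirac(study, [], ("A", "B"))


class TestPredictDirac:
    def _model(self, seed=0):
        spec = SynthSpec(n_networks=2, n_discriminative=1, seed=seed)
        study, nets, _ = generate_study(spec)
        return study, train_dirac(study, list(nets), ("A", "B"))

    def test_sample_matching_template_a_is_called_a(self):
        study, model = self._model()
        # build a profile realising template A's expected ordering
        genes = model.network.genes
        sample = study.values.loc[list(genes)].iloc[:, 0]
        # first A-sample at low noise matches its own template
        assert predict_dirac(model, study.values.iloc[:, 0]) == "A"
        assert predict_dirac(model, study.values[study.sample_ids[-1]]) == "B"

    def test_equidistant_sample_goes_to_b(self):
        """Delta = 0 (equal agreement with both templates) classifies as B."""
        from diracnet.core import RankTemplate, encode_sample

        from diracnet.classify import DiracModel

        net = GeneNetwork("N", ("G00", "G01", "G02"))
        sample = pd.Series({"G00": 1.0, "G01": 2.0, "G02": 3.0})
        enc = encode_sample(sample.to_numpy())  # (1,1,1)
        # templates each agree with the sample on exactly two of three pairs
        bits_a = np.array([1, 1, 0], dtype=np.uint8)
        bits_b = np.array([0, 1, 1], dtype=np.uint8)
        model = DiracModel(
            phenotype_a="A", phenotype_b="B", network=net,
            template_a=RankTemplate("N", "A", bits_a.astype(float), bits_a, 2),
            template_b=RankTemplate("N", "B", bits_b.astype(float), bits_b, 2),
            apparent_eta=0.5, tie_trace=[],
        )
        assert predict_dirac(model, sample) == "B"

    def test_prediction_invariant_to_monotone_transform(self):
        study, model = self._model(seed=9)
        for col in study.sample_ids[:5]:
            sample = study.values[col]
            transformed = np.exp(sample / 3.0) * 10 + 1
            assert predict_dirac(model, sample) == predict_dirac(
                model, transformed
            )

    def test_missing_genes_named_in_error(self):
        study, model = self._model()
        partial = study.values.iloc[:3, 0]
        with pytest.raises(KeyError, match=model.network.genes[-1]):
            predict_dirac(model, partial)


class TestWilcoxonFilter:
    def test_fully_separated_gene_ranked_first(self, rng):
        values = rng.normal(size=(10, 20))
        values[4, :10] += 50  # complete separation in gene 4
        study = make_study(values, labels=["A"] * 10 + ["B"] * 10)
        top = wilcoxon_top_genes(study, ("A", "B"), 3)
        assert top[0] == "G04"

    def test_requesting_all_genes_returns_all(self, rng):
        values = rng.normal(size=(5, 12))
        study = make_study(values, labels=["A"] * 6 + ["B"] * 6)
        assert sorted(wilcoxon_top_genes(study, ("A", "B"), 5)) == [
            f"G0{i}" for i in range(5)
        ]

    def test_null_selection_spreads_across_genes(self):
        """Identical class distributions: no gene should dominate the top
        slot across replicates."""
        first = []
        for rep in range(40):
            rng = np.random.default_rng(500 + rep)
            values = rng.normal(size=(8, 16))
            study = make_study(values, labels=["A"] * 8 + ["B"] * 8)
            first.append(wilcoxon_top_genes(study, ("A", "B"), 1)[0])
        assert len(set(first)) >= 4

    def test_too_many_genes_rejected(self, rng):
        study = make_study(rng.normal(size=(3, 8)), labels=["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError):
            wilcoxon_top_genes(study, ("A", "B"), 4)


class TestTsp:
    def test_planted_pair_scores_one_and_wins(self, rng):
        values = rng.normal(size=(6, 30))
        # plant a perfect reversal between G01 and G04
        values[1, :15] = values[4, :15] + 1.0   # A: G01 > G04
        values[1, 15:] = values[4, 15:] - 1.0   # B: G01 < G04
        study = make_study(values, labels=["A"] * 15 + ["B"] * 15)
        model = train_tsp(study, ("A", "B"))
        assert {model.gene_i, model.gene_j} == {"G01", "G04"}
        assert model.score == 1.0

    def test_score_matches_exhaustive_oracle_on_tiny_instances(self):
        """Best |Pr(X_i<X_j|A) - Pr(..|B)| over 4 genes equals a brute-force
        search over all 6 pairs."""
        for rep in range(20):
            rng = np.random.default_rng(700 + rep)
            values = rng.normal(size=(4, 12))
            labels = ["A"] * 6 + ["B"] * 6
            study = make_study(values, labels=labels)
            model = train_tsp(study, ("A", "B"))
            best = 0.0
            for i in range(4):
                for j in range(i + 1, 4):
                    p_a = np.mean(values[i, :6] < values[j, :6])
                    p_b = np.mean(values[i, 6:] < values[j, 6:])
                    best = max(best, abs(p_a - p_b))
            assert model.score == pytest.approx(best)

    def test_prediction_uses_learned_orientation(self, rng):
        values = rng.normal(size=(6, 30))
        values[1, :15] = values[4, :15] + 1.0
        values[1, 15:] = values[4, 15:] - 1.0
        study = make_study(values, labels=["A"] * 15 + ["B"] * 15)
        model = train_tsp(study, ("A", "B"))
        sample = pd.Series({"G01": 5.0, "G04": 1.0})
        assert predict_tsp(model, sample) == "A"
        assert predict_tsp(model, sample.iloc[::-1] * -1 + 10) == "B"

    def test_prediction_invariant_to_monotone_transform(self, rng):
        values = rng.normal(size=(5, 20))
        study = make_study(values, labels=["A"] * 10 + ["B"] * 10)
        model = train_tsp(study, ("A", "B"))
        sample = study.values.iloc[:, 3]
        assert predict_tsp(model, sample) == predict_tsp(model, np.exp(sample))


class TestLoocv:
    def test_separable_study_reaches_perfect_rate(self):
        spec = SynthSpec(
            n_networks=5, n_discriminative=1, n_samples_a=20,
            n_samples_b=20, sigma=0.25, seed=13,
        )
        study, nets, _ = generate_study(spec)
        result = loocv(study, list(nets), ("A", "B"), method="dirac")
        assert result.rate == 1.0

    def test_number_of_splits_equals_sample_count(self, planted_study):
        study, nets, _ = planted_study
        result = loocv(study, nets[:4], ("A", "B"), method="dirac")
        assert len(result.predictions) == study.n_samples

    def test_permuted_labels_give_chance_level_rate(self):
        """Destroying the label-signal association leaves DIRAC at ~0.5."""
        rates = []
        for rep in range(20):
            spec = SynthSpec(
                n_networks=5, n_discriminative=1, n_samples_a=20,
                n_samples_b=20, seed=40 + rep,
            )
            study, nets, _ = generate_study(spec)
            rng = np.random.default_rng(90 + rep)
            shuffled = rng.permutation(study.labels.to_numpy())
            study = ExpressionStudy(study.values).with_labels(list(shuffled))
            rates.append(loocv(study, list(nets), ("A", "B"), "dirac").rate)
        assert abs(np.mean(rates) - 0.5) < 0.1

    def test_no_leakage_held_out_values_do_not_affect_training(self):
        """Overwriting the held-out sample's values changes nothing about
        that split's trained model."""
        spec = SynthSpec(n_networks=4, n_discriminative=1, n_samples_a=5,
                         n_samples_b=5, seed=77)
        study, nets, _ = generate_study(spec)
        held_out = study.sample_ids[0]
        train_ids = study.sample_ids[1:]
        model_1 = train_dirac(study.subset_samples(train_ids), list(nets), ("A", "B"))
        poisoned = study.values.copy()
        poisoned[held_out] = 1234.5
        study_2 = ExpressionStudy(poisoned).with_labels(list(study.labels))
        model_2 = train_dirac(study_2.subset_samples(train_ids), list(nets), ("A", "B"))
        assert model_1.network.name == model_2.network.name
        assert np.array_equal(model_1.template_a.bits, model_2.template_a.bits)
        assert np.array_equal(model_1.template_b.bits, model_2.template_b.bits)

    def test_tsp_and_svm_comparators_run_on_separable_study(self):
        spec = SynthSpec(
            n_networks=3, n_discriminative=1, n_samples_a=10,
            n_samples_b=10, sigma=0.25, seed=21,
        )
        study, nets, _ = generate_study(spec)
        for method in ("tsp", "svm"):
            result = loocv(study, list(nets), ("A", "B"), method=method, seed=1)
            assert result.rate > 0.7

    def test_too_few_samples_rejected(self, rng):
        study = make_study(rng.normal(size=(4, 3)), labels=["A", "A", "B"])
        net = GeneNetwork("N", ("G00", "G01", "G02", "G03"))
        with pytest.raises(ValueError):
            loocv(study, [net], ("A", "B"))
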