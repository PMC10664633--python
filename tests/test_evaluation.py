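import numpy as np
import pytest

from conftest import make_table
from ddafuse.balance import BalanceConfig
from ddafuse.classifier import NetworkConfig
from ddafuse.core_data import (
    AssociationMatrix,
    EntityIndex,
    ParameterError,
    SimilarityMatrix,
    ValidationError,
)
from ddafuse.evaluation import (
    ConfusionCounts,
    classification_metrics,
    confusion_counts,
    cross_validate,
    curve_auc,
    kfold_split,
    new_drug_precision_at_1,
    singleton_drugs,
)
from ddafuse.pair_features import PROV_SYNTHETIC
from reference_impls import brute_top1_successes, mann_whitney_auroc

TINY_NET = NetworkConfig(hidden_layers=1, units_per_layer=8, epochs=2, batch_size=32, seed=0)
TINY_BAL = BalanceConfig(k_neighbors=3, seed=0)


class TestConfusionCounts:
    def test_mixed_example(self):
        c = confusion_counts(np.array([1, 1, 0, 0]), np.array([0.9, 0.2, 0.8, 0.1]), 0.5)
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_zero_threshold_leaves_no_negatives(self):
        c = confusion_counts(np.array([1, 0, 1]), np.array([0.3, 0.0, 0.9]), 0.0)
        assert c.FN == 0 and c.TN == 0

    def test_perfect_scores(self):
        c = confusion_counts(np.array([1, 0]), np.array([1.0, 0.0]), 0.5)
        assert c.FP == 0 and c.FN == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(np.array([]), np.array([]), 0.5)


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((50, 40, 5, 5), (0.9, 50 / 55, 50 / 55, 50 / 55)),
            ((1, 1, 1, 0), (2 / 3, 0.5, 1.0, 2 / 3)),
            ((0, 10, 0, 0), (1.0, 0.0, 0.0, 0.0)),  # degenerate denominators
            ((10, 0, 0, 0), (1.0, 1.0, 1.0, 1.0)),
            ((3, 3, 3, 3), (0.5, 0.5, 0.5, 0.5)),
        ],
    )
    def test_hand_computed_cases(self, counts, expected):
        c = ConfusionCounts(*counts)
        m = classification_metrics(c)
        assert m["accuracy"] == pytest.approx(expected[0], abs=1e-15)
        assert m["precision"] == pytest.approx(expected[1], abs=1e-15)
        assert m["recall"] == pytest.approx(expected[2], abs=1e-15)
        assert m["f1"] == pytest.approx(expected[3], abs=1e-15)

    def test_harmonic_mean_value(self):
        # precision 0.5, recall 1.0 -> F1 = 2/3
        m = classification_metrics(ConfusionCounts(TP=1, TN=0, FP=1, FN=0))
        assert m["f1"] == pytest.approx(2 / 3)


class TestCurveAuc:
    def test_perfect_ranking(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        assert curve_auc(labels, scores, "roc")[0] == 1.0
        assert curve_auc(labels, scores, "pr")[0] == 1.0

    def test_constant_scores_give_half_roc(self):
        labels = np.array([0, 1, 0, 1])
        assert curve_auc(labels, np.full(4, 0.5), "roc")[0] == pytest.approx(0.5)

    def test_known_interleaved_case(self):
        area = curve_auc(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.4, 0.2]), "roc")[0]
        assert area == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            curve_auc(np.ones(4), np.linspace(0, 1, 4), "roc")

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(10, 120)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            area = curve_auc(labels, scores, "roc")[0]
            assert area == pytest.approx(mann_whitney_auroc(labels, scores), abs=1e-10)


class TestKfoldSplit:
    def test_even_partition(self):
        folds = kfold_split(10, 5, seed=0)
        assert [len(f) for f in folds] == [2] * 5
        assert sorted(np.concatenate(folds)) == list(range(10))

    def test_remainder_distribution(self):
        folds = kfold_split(11, 5, seed=0)
        assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 3]

    def test_deterministic_per_seed(self):
        a = kfold_split(30, 4, seed=7)
        b = kfold_split(30, 4, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ParameterError):
            kfold_split(3, 5, seed=0)


class TestCrossValidate:
    def test_bookkeeping_and_aggregate(self, small_table):
        report = cross_validate(small_table, TINY_NET, TINY_BAL, k=5, rounds=1, seed=0)
        assert len(report.folds) == 5
        test_sizes = [f.counts.total for f in report.folds]
        assert sum(test_sizes) == small_table.n_rows
        agg = report.aggregate()
        manual = np.mean([f.auroc for f in report.folds])
        assert agg["auroc"]["mean"] == pytest.approx(manual, abs=1e-12)

    def test_multiple_rounds_reshuffle(self, small_table):
        report = cross_validate(small_table, TINY_NET, TINY_BAL, k=3, rounds=2, seed=0)
        assert len(report.folds) == 6
        assert {f.round_index for f in report.folds} == {0, 1}

    def test_balanced_table_rejected(self, small_table):
        bad = small_table.subset(np.arange(small_table.n_rows))
        bad.provenance[0] = PROV_SYNTHETIC
        with pytest.raises(ValidationError):
            cross_validate(bad, TINY_NET, TINY_BAL, k=3)

    def test_report_serializes(self, small_table, tmp_path):
        report = cross_validate(small_table, TINY_NET, TINY_BAL, k=3, rounds=1, seed=1)
        report.to_json(tmp_path / "metrics.json")
        assert (tmp_path / "metrics.json").stat().st_size > 0


class TestNewDrugExperiment:
    def build_assoc(self, Y):
        Y = np.asarray(Y)
        return AssociationMatrix(
            EntityIndex.from_ids([f"dr{i}" for i in range(Y.shape[0])]),
            EntityIndex.from_ids([f"di{j}" for j in range(Y.shape[1])]),
            Y,
        )

    def test_single_disease_always_succeeds(self):
        assoc = self.build_assoc(np.ones((4, 1), dtype=int))
        result = new_drug_precision_at_1(
            None, None, assoc, drugs=[0, 1, 2, 3], score_matrix=np.zeros((4, 1))
        )
        assert result.fraction == 1.0

    def test_oracle_scores_match_brute_force_enumeration(self, small_data):
        assoc = small_data.assoc
        cohort = singleton_drugs(assoc)
        assert cohort, "fixture must contain singleton drugs"
        result = new_drug_precision_at_1(
            None, None, assoc, drugs=cohort, score_matrix=small_data.affinity
        )
        held_out = {d: int(np.flatnonzero(assoc.Y[d])[0]) for d in cohort}
        assert result.successes == brute_top1_successes(small_data.affinity, held_out)

    def test_tie_broken_by_ascending_disease_index(self):
        assoc = self.build_assoc([[0, 1, 0]])
        scores = np.array([[0.5, 0.5, 0.5]])  # all tied: index 0 wins, not 1
        result = new_drug_precision_at_1(None, None, assoc, drugs=[0], score_matrix=scores)
        assert result.successes == 0

    def test_non_singleton_drug_rejected(self):
        assoc = self.build_assoc([[1, 1], [1, 0]])
        with pytest.raises(ValidationError):
            new_drug_precision_at_1(None, None, assoc, drugs=[0], score_matrix=np.zeros((2, 2)))

    def test_model_based_shared_mode_runs(self, small_data, small_fused):
        udrs, udis = small_fused
        cohort = singleton_drugs(small_data.assoc)
        result = new_drug_precision_at_1(
            udrs, udis, small_data.assoc, drugs=cohort,
            net_cfg=TINY_NET, bal_cfg=TINY_BAL, mode="shared",
        )
        assert result.total == len(cohort)
        assert 0.0 <= result.fraction <= 1.0
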