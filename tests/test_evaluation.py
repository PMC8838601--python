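"""Metrics: confusion rates, ROC/AUC, learner benchmark, end-to-end report."""

import numpy as np
import pytest

from hrqol_miner.evaluation import (
    ConfusionMatrix,
    UndefinedMetricError,
    benchmark_learners,
    confusion,
    f_measure,
    roc_auc,
    sensitivity,
    specificity,
)
from hrqol_miner.modeling import LearnerSpec
from hrqol_miner.synthetic import generate_feature_table


def pair_auc_oracle(y, s):
    """Exhaustive positive/negative pair counting, ties worth 1/2."""
    pos = [x for x, yi in zip(s, y) if yi]
    neg = [x for x, yi in zip(s, y) if not yi]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_confusion_counts(self):
        cm = confusion([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 1, 1, 1)
        assert cm.total == 5

    def test_perfect_sensitivity(self):
        assert sensitivity(ConfusionMatrix(tp=5, fp=0, tn=0, fn=0)) == 1.0

    def test_hand_computed_rates(self):
        cm = ConfusionMatrix(tp=3, fn=1, tn=4, fp=1)
        assert sensitivity(cm) == 0.75
        assert specificity(cm) == 0.8

    def test_f_measure_hand_value(self):
        # precision = recall = 3/4 -> F = 0.75
        assert f_measure(ConfusionMatrix(tp=3, fp=1, tn=0, fn=1)) == pytest.approx(0.75)

    @pytest.mark.parametrize(
        "metric,cm",
        [
            (sensitivity, ConfusionMatrix(0, 3, 2, 0)),
            (specificity, ConfusionMatrix(2, 0, 0, 3)),
            (f_measure, ConfusionMatrix(0, 0, 5, 2)),
        ],
    )
    def test_zero_denominators_raise_named_error(self, metric, cm):
        with pytest.raises(UndefinedMetricError):
            metric(cm)

    def test_rates_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.integers(0, 2, 30).astype(bool)
            p = rng.integers(0, 2, 30).astype(bool)
            cm = confusion(y, p)
            if cm.tp + cm.fn > 0:
                assert 0 <= sensitivity(cm) <= 1
            if cm.tn + cm.fp > 0:
                assert 0 <= specificity(cm) <= 1


class TestRocAuc:
    def test_perfect_ranking(self):
        curve = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert curve.auc == 1.0

    def test_tied_scores_half_credit(self):
        # one tied positive/negative pair out of four -> 0.875
        curve = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.8, 0.3])
        assert curve.auc == pytest.approx(0.875)

    def test_matches_pair_oracle_to_1e12(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = np.concatenate([[True, False], rng.random(n) < 0.5])
            s = np.round(rng.random(n + 2), 2)  # rounding forces ties
            assert roc_auc(y, s).auc == pytest.approx(pair_auc_oracle(y, s), abs=1e-12)

    def test_trapezoid_integral_equals_pair_statistic(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            y = np.concatenate([[True, False], rng.random(n) < 0.4])
            s = np.round(rng.random(n + 2), 1)
            curve = roc_auc(y, s)
            fpr = np.array([p[0] for p in curve.points])
            tpr = np.array([p[1] for p in curve.points])
            assert np.trapezoid(tpr, fpr) == pytest.approx(curve.auc, abs=1e-12)

    def test_random_scores_center_on_half(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(2000):
            y = np.concatenate([[True, False], rng.random(18) < 0.5])
            s = rng.random(20)
            aucs.append(roc_auc(y, s).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(4)
        y = rng.random(30) < 0.5
        y[:2] = [True, False]
        s = rng.random(30)  # continuous, ties almost surely absent
        assert roc_auc(y, s).auc + roc_auc(y, -s).auc == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([[True, False], rng.random(28) < 0.5])
        s = rng.random(30)
        assert roc_auc(y, np.exp(3 * s)).auc == pytest.approx(roc_auc(y, s).auc)

    def test_curve_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([[True, False], rng.random(28) < 0.5])
        curve = roc_auc(y, np.round(rng.random(30), 1))
        fpr = [p[0] for p in curve.points]
        tpr = [p[1] for p in curve.points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestBenchmarkLearners:
    FAST_FAMILIES = [
        LearnerSpec("knn"),
        LearnerSpec("svm"),
        LearnerSpec("mlp", {"hidden_units": 8}),
        LearnerSpec("random_forest", {"n_trees": 50}),
        LearnerSpec("gradient_boosting", {"n_rounds": 30}),
    ]

    def test_separable_data_near_one_for_all_families(self):
        X, y, _ = generate_feature_table(200, 2, 2, effect_size=4.0, seed=7)
        table = benchmark_learners(X.to_numpy(), y, self.FAST_FAMILIES, seed=0)
        assert set(table["family"]) == {s.family for s in self.FAST_FAMILIES}
        assert (table["mean_auc"] > 0.95).all()

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(8)
        X, y, _ = generate_feature_table(300, 2, 2, effect_size=3.0, seed=8)
        y_shuffled = rng.permutation(y)
        table = benchmark_learners(X.to_numpy(), y_shuffled, self.FAST_FAMILIES, seed=0)
        assert (abs(table["mean_auc"] - 0.5) < 0.15).all()

    def test_deterministic(self):
        X, y, _ = generate_feature_table(120, 1, 2, effect_size=2.0, seed=9)
        t1 = benchmark_learners(X.to_numpy(), y, self.FAST_FAMILIES, seed=1)
        t2 = benchmark_learners(X.to_numpy(), y, self.FAST_FAMILIES, seed=1)
        import pandas as pd

        pd.testing.assert_frame_equal(t1, t2)

    def test_default_families_cover_all_five(self):
        X, y, _ = generate_feature_table(60, 1, 1, effect_size=3.0, seed=10)
        table = benchmark_learners(X.to_numpy(), y, folds=3, seed=0)
        assert list(table["family"]) == [
            "knn", "svm", "mlp", "random_forest", "gradient_boosting",
        ]


class TestEvaluateModel:
    def test_constant_negative_model(self, small_synth, lexset):
        """A model that never flags anything: sensitivity 0, specificity 1."""
        from hrqol_miner.evaluation import evaluate_model
        from hrqol_miner.modeling import DimensionModel, HierarchicalModel, TrainingConfig
        from hrqol_miner.features import FEATURE_NAMES, extract_features, fit_normalization

        class NeverFires:
            def predict_proba(self, X):
                return np.column_stack([np.ones(len(X)), np.zeros(len(X))])

        X = extract_features(small_synth.corpus, lexset)
        norm = fit_normalization(X)
        stub = DimensionModel("impact", NeverFires(), ["lex_physical"], {}, 0.5)
        model = HierarchicalModel(
            impact_model=stub,
            dimension_models={
                d: DimensionModel(d, None, [], {}, float("nan"), untrainable=True)
                for d in ("physical", "psychic", "activity", "relational", "financial")
            },
            normalization=norm,
            lexset=lexset,
            threshold=0.5,
            feature_names=list(FEATURE_NAMES),
            config=TrainingConfig(),
            seed=0,
        )
        report = evaluate_model(model, small_synth.corpus, small_synth.labels)
        impact = report.targets["impact"]
        assert impact.sensitivity == 0.0
        assert impact.specificity == 1.0
        assert impact.f_measure is None  # no positive predictions

    def test_no_label_overlap_rejected(self, small_synth, lexset):
        from hrqol_miner.corpus_io import Corpus, Message
        from hrqol_miner.evaluation import evaluate_model
        from hrqol_miner.modeling import TrainingConfig, train_hierarchical

        cfg = TrainingConfig(grid={"n_rounds": [20]}, sffs_max_features=2,
                             selection_hyperparameters={"n_rounds": 20})
        model = train_hierarchical(small_synth.corpus, small_synth.labels, lexset, cfg, seed=1)
        stranger = Corpus([Message("zz", "bonjour tout le monde")])
        with pytest.raises(ValueError, match="overlap"):
            evaluate_model(model, stranger, small_synth.labels)
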