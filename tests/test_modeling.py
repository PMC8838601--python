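"""SMOTE, SFFS feature selection, grid search, and the hierarchical model."""

import numpy as np
import pandas as pd
import pytest

from hrqol_miner.corpus_io import split_corpus
from hrqol_miner.lexicons import DIMENSIONS
from hrqol_miner.modeling import (
    DEFAULT_GRID,
    LearnerSpec,
    SmoteError,
    TrainingConfig,
    grid_search,
    load_model,
    predict,
    predictions_to_frame,
    save_model,
    sffs_select,
    smote_oversample,
    train_hierarchical,
)
from hrqol_miner.synthetic import GeneratorSpec, generate_corpus, generate_feature_table

FAST_SPEC = LearnerSpec("gradient_boosting", {"n_rounds": 30, "n_trees_max_depth": 2})
FAST_CFG = TrainingConfig(
    grid={"learning_rate": [0.3], "n_rounds": [30]},
    sffs_max_features=3,
    selection_hyperparameters={"n_rounds": 30, "n_trees_max_depth": 2},
)


def on_segment(p, a, b, tol=1e-9):
    """Is p a convex combination of a and b?"""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.allclose(p, a, atol=tol)
    t = float((p - a) @ ab) / denom
    return -tol <= t <= 1 + tol and np.allclose(a + t * ab, p, atol=tol)


class TestSmote:
    def test_balances_minority_to_majority(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 3))
        y = np.array([1] * 3 + [0] * 9)
        X2, y2 = smote_oversample(X, y, k=2, seed=0)
        assert np.sum(y2 == 1) == np.sum(y2 == 0) == 9

    def test_already_balanced_unchanged(self):
        X = np.arange(12.0).reshape(6, 2)
        y = np.array([0, 1, 0, 1, 0, 1])
        X2, y2 = smote_oversample(X, y, k=1, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_originals_preserved_verbatim(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 4))
        y = np.array([1] * 4 + [0] * 6)
        X2, _ = smote_oversample(X, y, k=3, seed=5)
        assert np.array_equal(X2[:10], X)

    def test_synthetic_rows_lie_on_minority_segments(self):
        """Exhaustive pairwise-segment membership oracle on a 5-point minority."""
        rng = np.random.default_rng(2)
        X_min = rng.random((5, 3))
        X_maj = rng.random((20, 3)) + 5.0
        X = np.vstack([X_min, X_maj])
        y = np.array([1] * 5 + [0] * 20)
        X2, y2 = smote_oversample(X, y, k=4, seed=3)
        synthetic = X2[len(X) :]
        assert len(synthetic) == 15
        for p in synthetic:
            assert any(
                on_segment(p, X_min[i], X_min[j])
                for i in range(5)
                for j in range(i + 1, 5)
            )

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.random((15, 2))
        y = np.array([1] * 4 + [0] * 11)
        a = smote_oversample(X, y, k=3, seed=9)
        b = smote_oversample(X, y, k=3, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_single_sample_minority_rejected(self):
        X = np.random.default_rng(0).random((5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(SmoteError, match="minority"):
            smote_oversample(X, y, k=5, seed=0)


class TestSffs:
    def test_separating_feature_selected_first(self):
        rng = np.random.default_rng(4)
        n = 120
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame({f"noise_{i}": rng.normal(size=n) for i in range(5)})
        X.insert(2, "signal", y + rng.normal(scale=0.01, size=n))
        result = sffs_select(X, y, FAST_SPEC, seed=0, max_features=3)
        assert result.trajectory[0][2] == "signal"
        assert "signal" in result.selected

    def test_single_feature_set(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 20)
        X = pd.DataFrame({"only": y + rng.normal(scale=0.1, size=40)})
        result = sffs_select(X, y, FAST_SPEC, seed=0)
        assert result.selected == ["only"]

    def test_accepted_scores_non_decreasing(self):
        X, y, _ = generate_feature_table(150, 2, 6, effect_size=1.0, seed=6)
        result = sffs_select(X, y, FAST_SPEC, seed=1, max_features=5)
        scores = [s for _, _, _, s in result.trajectory]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_invariant_to_appended_constant_features(self):
        X, y, _ = generate_feature_table(120, 2, 3, effect_size=2.0, seed=7)
        base = sffs_select(X, y, FAST_SPEC, seed=2, max_features=4)
        X_aug = X.copy()
        X_aug["const_a"] = 0.0
        X_aug["const_b"] = 1.0
        augmented = sffs_select(X_aug, y, FAST_SPEC, seed=2, max_features=4)
        assert augmented.selected == base.selected

    def test_degenerate_labels_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            sffs_select(X, np.zeros(3, dtype=int), FAST_SPEC)


class TestGridSearch:
    def _toy(self):
        X, y, _ = generate_feature_table(100, 2, 1, effect_size=4.0, seed=8)
        return X.to_numpy(), y

    def test_single_point_grid(self):
        X, y = self._toy()
        best, table = grid_search(X, y, "gradient_boosting", {"n_rounds": [25]}, seed=0)
        assert best == {"n_rounds": 25}
        assert len(table) == 1

    def test_winning_setting_on_separable_data(self):
        X, y = self._toy()
        best, table = grid_search(
            X, y, "gradient_boosting", {"n_rounds": [5, 50], "learning_rate": [0.3]}, seed=0
        )
        assert table["mean_auc"].max() == table.loc[
            (table["n_rounds"] == best["n_rounds"]), "mean_auc"
        ].iloc[0]

    def test_deterministic_cv_table(self):
        X, y = self._toy()
        grid = {"n_rounds": [10, 20]}
        _, t1 = grid_search(X, y, "gradient_boosting", grid, seed=3)
        _, t2 = grid_search(X, y, "gradient_boosting", grid, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_grid_key_rejected(self):
        X, y = self._toy()
        with pytest.raises(ValueError, match="unknown grid keys"):
            grid_search(X, y, "gradient_boosting", {"n_epochs_typo": [1]}, seed=0)


class TestLearnerSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec("deep_transformer")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec("knn", {"learning_rate": 0.1})

    def test_gradient_boosting_exposes_all_knobs(self):
        spec = LearnerSpec(
            "gradient_boosting",
            {
                "learning_rate": 0.1,
                "n_rounds": 10,
                "n_trees_max_depth": 2,
                "min_child_weight": 1,
                "min_split_loss": 0,
                "l1_regularization": 0.5,
            },
        )
        from hrqol_miner.modeling import make_learner

        est = make_learner(spec, seed=0)
        assert est.get_params()["reg_alpha"] == 0.5


@pytest.fixture(scope="module")
def trained():
    synth = generate_corpus(GeneratorSpec(n=220, seed=21))
    split = split_corpus(synth.corpus, 0.7, seed=21)
    from hrqol_miner.lexicons import bundled_lexicons

    lexset = bundled_lexicons()
    model = train_hierarchical(split.train, synth.labels, lexset, FAST_CFG, seed=21)
    return synth, split, model


class TestHierarchicalModel:
    def test_dimension_models_use_their_lexical_feature(self, trained):
        _, _, model = trained
        for d, m in model.dimension_models.items():
            if not m.untrainable:
                assert f"lex_{d}" in m.selected

    def test_gating_invariant(self, trained):
        synth, split, model = trained
        for p in predict(model, split.validation):
            if not p.impact_flag:
                assert not any(p.dimension_flags.values())
                assert p.dimension_probs == {}

    def test_high_signal_corpus_predicted_correctly(self, trained):
        synth, split, model = trained
        by_id = {lab.message_id: lab for lab in synth.labels}
        preds = predict(model, split.validation)
        agree = np.mean([p.impact_flag == by_id[p.message_id].impact for p in preds])
        assert agree > 0.9

    def test_empty_corpus_predicts_nothing(self, trained):
        from hrqol_miner.corpus_io import Corpus

        _, _, model = trained
        assert predict(model, Corpus([])) == []

    def test_untrainable_dimension_forced_false(self, lexset):
        synth = generate_corpus(
            GeneratorSpec(
                n=150,
                prevalence={
                    "impact": 0.5, "physical": 0.3, "psychic": 0.3,
                    "activity": 0.2, "relational": 0.1, "financial": 0.0,
                },
                seed=22,
            )
        )
        cfg = TrainingConfig(
            grid={"n_rounds": [30]}, sffs_max_features=2,
            selection_hyperparameters={"n_rounds": 30},
        )
        model = train_hierarchical(synth.corpus, synth.labels, lexset, cfg, seed=22)
        assert model.dimension_models["financial"].untrainable
        assert not model.dimension_models["physical"].untrainable
        for p in predict(model, synth.corpus):
            assert p.dimension_flags["financial"] is False

    def test_model_round_trip_preserves_predictions(self, trained, tmp_path):
        synth, split, model = trained
        save_model(model, tmp_path / "model")
        reloaded = load_model(tmp_path / "model")
        f1 = predictions_to_frame(predict(model, split.validation))
        f2 = predictions_to_frame(predict(reloaded, split.validation))
        pd.testing.assert_frame_equal(f1, f2)

    def test_training_is_deterministic(self, lexset):
        synth = generate_corpus(GeneratorSpec(n=150, seed=23))
        models = [
            train_hierarchical(synth.corpus, synth.labels, lexset, FAST_CFG, seed=23)
            for _ in range(2)
        ]
        frames = [predictions_to_frame(predict(m, synth.corpus)) for m in models]
        pd.testing.assert_frame_equal(frames[0], frames[1])
        assert models[0].provenance == models[1].provenance


class TestFeatureTable:
    def test_deterministic(self):
        a = generate_feature_table(50, 2, 3, seed=1)
        b = generate_feature_table(50, 2, 3, seed=1)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_zero_effect_gives_chance_auc(self):
        X, y, _ = generate_feature_table(400, 2, 2, effect_size=0.0, seed=2)
        from hrqol_miner.modeling import cv_auc

        mean, _ = cv_auc(X.to_numpy(), y, FAST_SPEC, seed=0)
        assert abs(mean - 0.5) < 0.15

    def test_too_few_minority_rejected(self):
        with pytest.raises(ValueError):
            generate_feature_table(50, 1, 1, imbalance=0.01)
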