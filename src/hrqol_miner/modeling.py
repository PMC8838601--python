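"""Hierarchical impact/dimension classification.

The classifier is two-stage ("gated"): a first binary model decides whether a
message mentions any impact on health-related quality of life; messages
flagged positive are passed to five per-dimension binary models (physical,
psychic, activity, relational, financial). Each model is built the same way:

1. max-normalized, median-imputed features (fit on training rows only);
2. sequential forward floating selection (SFFS) scored by 5-fold
   cross-validated AUC — greedy feature addition with conditional backward
   removal;
3. a 5-fold cross-validated grid search over the learner's hyperparameters;
4. a final fit on the full training set.

Rare dimensions (by default activity, relational and financial) are
rebalanced with SMOTE: synthetic minority rows interpolated between minority
nearest neighbors. Oversampling happens inside training folds only, never on
validation folds, to avoid optimistic cross-validation.

Five learner families are supported (k-nearest neighbors, SVM, multi-layer
perceptron, random forest, gradient boosting); gradient boosting (XGBoost)
is the default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .annotation import AnnotationLabel
from .corpus_io import Corpus
from .features import (
    FEATURE_NAMES,
    NormalizationState,
    apply_normalization,
    extract_features,
    fit_normalization,
)
from .lexicons import DIMENSIONS, LexiconSet, save_lexicons, load_lexicons

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "LearnerSpec",
    "SelectionResult",
    "TrainingConfig",
    "DimensionModel",
    "HierarchicalModel",
    "ImpactPrediction",
    "SmoteError",
    "make_learner",
    "decision_scores",
    "smote_oversample",
    "cv_auc",
    "sffs_select",
    "grid_search",
    "train_hierarchical",
    "predict",
    "predictions_to_frame",
    "save_model",
    "load_model",
    "DEFAULT_GRID",
    "FULL_GRID",
]

FAMILIES = ("knn", "svm", "mlp", "random_forest", "gradient_boosting")

#: Tunable hyperparameters per family (grid keys are validated against this).
FAMILY_PARAMS: dict[str, dict[str, str]] = {
    "knn": {"n_neighbors": "n_neighbors"},
    "svm": {"c": "C", "gamma": "gamma"},
    "mlp": {"hidden_units": "hidden_units", "l2_regularization": "alpha"},
    "random_forest": {"n_trees": "n_estimators", "max_depth": "max_depth"},
    # gradient boosting knob names follow the boosting literature: number of
    # rounds (epochs), tree depth, minimum child weight, minimum split loss,
    # L1 regularization
    "gradient_boosting": {
        "learning_rate": "learning_rate",
        "n_rounds": "n_estimators",
        "n_trees_max_depth": "max_depth",
        "min_child_weight": "min_child_weight",
        "min_split_loss": "gamma",
        "l1_regularization": "reg_alpha",
    },
}

#: Compact default grid for the gradient-boosting models.
DEFAULT_GRID: dict[str, list] = {
    "learning_rate": [0.1, 0.3],
    "n_rounds": [50, 100],
    "n_trees_max_depth": [2, 4],
}

#: Wide grid over every exposed boosting knob.
FULL_GRID: dict[str, list] = {
    "learning_rate": [0.05, 0.1, 0.3],
    "n_rounds": [50, 100, 200],
    "n_trees_max_depth": [2, 4, 6],
    "min_child_weight": [1, 5],
    "min_split_loss": [0, 1],
    "l1_regularization": [0, 0.5],
}


class SmoteError(ValueError):
    """SMOTE cannot run (e.g. a single-sample minority class)."""


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family plus hyperparameter overrides."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; choose from {FAMILIES}")
        unknown = set(self.hyperparameters) - set(FAMILY_PARAMS[self.family])
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}; "
                f"known: {sorted(FAMILY_PARAMS[self.family])}"
            )


def make_learner(spec: LearnerSpec, seed: int = 0):
    """Instantiate a fresh scikit-learn / XGBoost estimator for a spec."""
    hp = spec.hyperparameters
    if spec.family == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=int(hp.get("n_neighbors", 5)))
    if spec.family == "svm":
        from sklearn.svm import SVC

        return SVC(
            C=float(hp.get("c", 1.0)),
            gamma=hp.get("gamma", "scale"),
            random_state=seed,
        )
    if spec.family == "mlp":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            hidden_layer_sizes=(int(hp.get("hidden_units", 32)),),
            alpha=float(hp.get("l2_regularization", 1e-4)),
            max_iter=500,
            random_state=seed,
        )
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=int(hp.get("n_trees", 200)),
            max_depth=hp.get("max_depth"),
            random_state=seed,
            n_jobs=1,
        )
    # gradient boosting
    from xgboost import XGBClassifier

    return XGBClassifier(
        learning_rate=float(hp.get("learning_rate", 0.3)),
        n_estimators=int(hp.get("n_rounds", 50)),
        max_depth=int(hp.get("n_trees_max_depth", 3)),
        min_child_weight=float(hp.get("min_child_weight", 1)),
        gamma=float(hp.get("min_split_loss", 0)),
        reg_alpha=float(hp.get("l1_regularization", 0)),
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )


def decision_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class scores for ranking (probability or margin)."""
    if hasattr(estimator, "predict_proba"):
        return np.asarray(estimator.predict_proba(X))[:, 1]
    return np.asarray(estimator.decision_function(X))


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the k nearest minority neighbors of ``x`` (Euclidean
    distance on the normalized features). The minority class is raised to the
    majority count; original rows are preserved verbatim; an already balanced
    input is returned unchanged. Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-d with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE needs exactly 2 classes, got {list(classes)}")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    majority_count = counts.max()
    idx_min = np.flatnonzero(y == minority)
    m = len(idx_min)
    if m < 2:
        raise SmoteError(f"minority class {minority} has {m} sample(s); SMOTE needs >= 2")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, m - 1)
    if k_eff < k:
        logger.info("smote_oversample: k reduced from %d to %d (minority size %d)", k, k_eff, m)

    X_min = X[idx_min]
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    n_needed = int(majority_count - m)
    base = rng.integers(0, m, size=n_needed)
    pick = rng.integers(0, k_eff, size=n_needed)
    u = rng.random(size=n_needed)
    x_base = X_min[base]
    x_nn = X_min[neighbors[base, pick]]
    synthetic = x_base + u[:, None] * (x_nn - x_base)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Cross-validated AUC, SFFS, grid search
# ---------------------------------------------------------------------------


def cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    spec: LearnerSpec,
    folds: int = 5,
    seed: int = 0,
    smote_k: Optional[int] = None,
) -> tuple[float, list[float]]:
    """Mean AUC over stratified folds; SMOTE (if requested) applies to the
    training half of each fold only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present")
    # cap folds at the minority count so every validation fold holds both classes
    eff_folds = min(folds, int(counts.min()))
    if eff_folds < 2:
        raise ValueError(f"minority class too small for cross-validation ({counts.min()})")
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    scores = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[tr], y[tr]
        if smote_k is not None and np.unique(y_tr, return_counts=True)[1].min() >= 2:
            X_tr, y_tr = smote_oversample(X_tr, y_tr, k=smote_k, seed=seed + fold)
        est = make_learner(spec, seed=seed)
        est.fit(X_tr, y_tr)
        scores.append(float(roc_auc_score(y[va], decision_scores(est, X[va]))))
    return float(np.mean(scores)), scores


@dataclass
class SelectionResult:
    """Outcome of sequential forward floating selection."""

    selected: list[str]
    cv_score: float
    trajectory: list[tuple[int, str, str, float]]  # (step, "add"/"remove", feature, score)


_EPS = 1e-12


def sffs_select(
    X: pd.DataFrame,
    y: Sequence,
    spec: LearnerSpec,
    folds: int = 5,
    seed: int = 0,
    max_features: Optional[int] = None,
    smote_k: Optional[int] = None,
) -> SelectionResult:
    """Sequential forward floating selection scored by cross-validated AUC.

    Repeat: add the feature maximizing CV AUC; then conditionally remove any
    feature whose removal strictly improves the score (never the one just
    added). Stop when no addition improves the score or ``max_features`` is
    reached. Ties break by feature-inventory (column) order. Accepted steps
    have non-decreasing scores.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs both classes in y")
    feature_order = list(X.columns)
    if len(feature_order) < 1:
        raise ValueError("no candidate features")

    def score(subset: list[str]) -> float:
        return cv_auc(X[subset].to_numpy(), y, spec, folds=folds, seed=seed, smote_k=smote_k)[0]

    selected: list[str] = []
    current = -np.inf
    trajectory: list[tuple[int, str, str, float]] = []
    step = 0
    while True:
        if max_features is not None and len(selected) >= max_features:
            break
        candidates = [f for f in feature_order if f not in selected]
        if not candidates:
            break
        best_feature, best_score = None, -np.inf
        for f in candidates:  # inventory order -> deterministic tie-break
            s = score(selected + [f])
            if s > best_score + _EPS:
                best_feature, best_score = f, s
        if best_feature is None or best_score <= current + _EPS:
            break
        selected.append(best_feature)
        current = best_score
        step += 1
        trajectory.append((step, "add", best_feature, current))

        # floating backward step
        improved = True
        while improved and len(selected) > 2:
            improved = False
            best_removal, best_removal_score = None, current
            for f in selected[:-1]:  # never the feature just added
                s = score([g for g in selected if g != f])
                if s > best_removal_score + _EPS:
                    best_removal, best_removal_score = f, s
            if best_removal is not None:
                selected.remove(best_removal)
                current = best_removal_score
                step += 1
                trajectory.append((step, "remove", best_removal, current))
                improved = True
    if not selected:
        # degenerate signal: keep the single best feature anyway
        scores = [(score([f]), -i) for i, f in enumerate(feature_order)]
        best_idx = int(-max(scores)[1])
        selected = [feature_order[best_idx]]
        current = score(selected)
        trajectory.append((1, "add", selected[0], current))
    return SelectionResult(selected=selected, cv_score=float(current), trajectory=trajectory)


def grid_search(
    X: np.ndarray,
    y: Sequence,
    family: str,
    grid: dict[str, list],
    folds: int = 5,
    seed: int = 0,
    smote_k: Optional[int] = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search by mean cross-validated AUC.

    The same stratified folds are reused for every grid point. The best
    setting is the maximum mean AUC, ties resolved by grid iteration order.
    Returns (best hyperparameters, full CV table with fold-level scores).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    unknown = set(grid) - set(FAMILY_PARAMS[family])
    if unknown:
        raise ValueError(
            f"unknown grid keys for {family}: {sorted(unknown)}; "
            f"known: {sorted(FAMILY_PARAMS[family])}"
        )
    keys = list(grid.keys())
    rows = []
    best_params: Optional[dict] = None
    best_score = -np.inf
    for values in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        mean, fold_scores = cv_auc(
            X, y, LearnerSpec(family, params), folds=folds, seed=seed, smote_k=smote_k
        )
        row = dict(params)
        row["mean_auc"] = mean
        for i, s in enumerate(fold_scores):
            row[f"fold_{i}"] = s
        rows.append(row)
        if mean > best_score + _EPS:
            best_params, best_score = params, mean
    assert best_params is not None
    return best_params, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hierarchical model
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    """Configuration for the two-stage training pipeline."""

    learner_family: str = "gradient_boosting"
    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    smote_dimensions: tuple[str, ...] = ("activity", "relational", "financial")
    smote_k: int = 5
    folds: int = 5
    threshold: float = 0.5
    sffs_max_features: int = 6
    # hyperparameters of the learner used *during* feature selection
    selection_hyperparameters: dict = field(
        default_factory=lambda: {"n_rounds": 50, "n_trees_max_depth": 3}
    )
    stage2_on_impacted: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("decision threshold must lie in (0, 1)")
        for d in self.smote_dimensions:
            if d not in DIMENSIONS:
                raise ValueError(f"unknown SMOTE dimension {d!r}")


@dataclass
class DimensionModel:
    name: str
    estimator: Optional[object]
    selected: list[str]
    best_params: dict
    cv_score: float
    untrainable: bool = False


@dataclass
class HierarchicalModel:
    """Fitted two-stage classifier with full provenance."""

    impact_model: DimensionModel
    dimension_models: dict[str, DimensionModel]
    normalization: NormalizationState
    lexset: LexiconSet
    threshold: float
    feature_names: list[str]
    config: TrainingConfig
    seed: int
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ImpactPrediction:
    """Gated prediction: dimension outputs exist only for flagged messages."""

    message_id: str
    impact_prob: float
    impact_flag: bool
    dimension_probs: dict[str, float]  # empty when impact_flag is False
    dimension_flags: dict[str, bool]


def _labels_by_id(labels: Iterable[AnnotationLabel]) -> dict[str, AnnotationLabel]:
    return {lab.message_id: lab for lab in labels}


def _train_single(
    name: str,
    X: pd.DataFrame,
    y: np.ndarray,
    config: TrainingConfig,
    seed: int,
    smote_k: Optional[int],
) -> DimensionModel:
    selection_spec = LearnerSpec(config.learner_family, config.selection_hyperparameters)
    sel = sffs_select(
        X,
        y,
        selection_spec,
        folds=config.folds,
        seed=seed,
        max_features=config.sffs_max_features,
        smote_k=smote_k,
    )
    X_sel = X[sel.selected].to_numpy()
    best_params, _cv_table = grid_search(
        X_sel,
        y,
        config.learner_family,
        config.grid,
        folds=config.folds,
        seed=seed,
        smote_k=smote_k,
    )
    X_fit, y_fit = X_sel, y
    if smote_k is not None and np.unique(y, return_counts=True)[1].min() >= 2:
        X_fit, y_fit = smote_oversample(X_fit, y_fit, k=smote_k, seed=seed)
    est = make_learner(LearnerSpec(config.learner_family, best_params), seed=seed)
    est.fit(X_fit, y_fit)
    return DimensionModel(
        name=name,
        estimator=est,
        selected=sel.selected,
        best_params=best_params,
        cv_score=sel.cv_score,
    )


def train_hierarchical(
    corpus: Corpus,
    labels: Iterable[AnnotationLabel],
    lexset: LexiconSet,
    config: Optional[TrainingConfig] = None,
    seed: int = 0,
) -> HierarchicalModel:
    """Train the gated two-stage classifier on a (training) corpus.

    Stage 1 learns the overall impact flag on all messages. Each stage-2
    dimension model is trained, by default, on the subset of training messages
    labeled impacted (positives: the dimension flag). SMOTE applies only to
    the configured rare dimensions, and only within training folds. A
    dimension with fewer than two positive training labels is marked
    untrainable: its predictions are fixed to False.
    """
    config = config or TrainingConfig()
    by_id = _labels_by_id(labels)
    missing = [m.id for m in corpus if m.id not in by_id]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} training messages, e.g. {missing[:3]}")

    X_raw = extract_features(corpus, lexset)
    norm = fit_normalization(X_raw, fitted_on=corpus.provenance)
    X = apply_normalization(X_raw, norm)
    ids = corpus.ids()
    y_impact = np.array([by_id[i].impact for i in ids], dtype=int)

    seed_rng = np.random.default_rng(seed)
    stage_seeds = {name: int(seed_rng.integers(2**31)) for name in ("impact", *DIMENSIONS)}

    logger.info("training stage-1 impact model (n=%d)", len(X))
    impact_model = _train_single(
        "impact", X, y_impact, config, seed=stage_seeds["impact"], smote_k=None
    )

    if config.stage2_on_impacted:
        stage2_mask = y_impact == 1
    else:
        stage2_mask = np.ones(len(ids), dtype=bool)
    X2 = X.loc[stage2_mask]
    ids2 = [i for i, keep in zip(ids, stage2_mask) if keep]

    dimension_models: dict[str, DimensionModel] = {}
    for d in DIMENSIONS:
        y_d = np.array([by_id[i].dimensions.get(d, False) for i in ids2], dtype=int)
        n_pos, n_neg = int(y_d.sum()), int(len(y_d) - y_d.sum())
        if n_pos < 2 or n_neg < 2:
            logger.warning("dimension %s untrainable (%d pos / %d neg)", d, n_pos, n_neg)
            dimension_models[d] = DimensionModel(
                name=d, estimator=None, selected=[], best_params={}, cv_score=float("nan"),
                untrainable=True,
            )
            continue
        smote_k = config.smote_k if d in config.smote_dimensions else None
        logger.info("training stage-2 model for %s (n=%d, pos=%d)", d, len(y_d), n_pos)
        dimension_models[d] = _train_single(
            d, X2, y_d, config, seed=stage_seeds[d], smote_k=smote_k
        )

    provenance = {
        "seed": seed,
        "stage_seeds": stage_seeds,
        "n_train": len(ids),
        "config": {
            "learner_family": config.learner_family,
            "grid": config.grid,
            "smote_dimensions": list(config.smote_dimensions),
            "smote_k": config.smote_k,
            "folds": config.folds,
            "threshold": config.threshold,
            "sffs_max_features": config.sffs_max_features,
            "stage2_on_impacted": config.stage2_on_impacted,
        },
        "selected": {
            "impact": impact_model.selected,
            **{d: m.selected for d, m in dimension_models.items()},
        },
    }
    return HierarchicalModel(
        impact_model=impact_model,
        dimension_models=dimension_models,
        normalization=norm,
        lexset=lexset,
        threshold=config.threshold,
        feature_names=list(FEATURE_NAMES),
        config=config,
        seed=seed,
        provenance=provenance,
    )


def predict(model: HierarchicalModel, corpus: Corpus) -> list[ImpactPrediction]:
    """Gated prediction for a normalized corpus.

    Stage 1 produces an impact probability; ``impact_flag`` is
    ``prob >= threshold``. Stage-2 models run only for flagged messages, so
    an unflagged message has no dimension probabilities and all dimension
    flags False (the gating invariant).
    """
    if len(corpus) == 0:
        return []
    X_raw = extract_features(corpus, model.lexset)
    if list(X_raw.columns) != model.feature_names:
        raise ValueError("feature inventory mismatch between corpus features and model")
    X = apply_normalization(X_raw, model.normalization)
    ids = corpus.ids()

    impact_probs = decision_scores(
        model.impact_model.estimator, X[model.impact_model.selected].to_numpy()
    )
    flags = impact_probs >= model.threshold

    dim_probs_all: dict[str, np.ndarray] = {}
    flagged_idx = np.flatnonzero(flags)
    for d, dm in model.dimension_models.items():
        probs = np.full(len(ids), np.nan)
        if not dm.untrainable and len(flagged_idx):
            probs[flagged_idx] = decision_scores(
                dm.estimator, X.iloc[flagged_idx][dm.selected].to_numpy()
            )
        dim_probs_all[d] = probs

    predictions = []
    for i, mid in enumerate(ids):
        flagged = bool(flags[i])
        dim_probs: dict[str, float] = {}
        dim_flags: dict[str, bool] = {d: False for d in DIMENSIONS}
        if flagged:
            for d, dm in model.dimension_models.items():
                if dm.untrainable:
                    continue
                p = float(dim_probs_all[d][i])
                dim_probs[d] = p
                dim_flags[d] = p >= model.threshold
        predictions.append(
            ImpactPrediction(
                message_id=mid,
                impact_prob=float(impact_probs[i]),
                impact_flag=flagged,
                dimension_probs=dim_probs,
                dimension_flags=dim_flags,
            )
        )
    return predictions


def predictions_to_frame(predictions: Iterable[ImpactPrediction]) -> pd.DataFrame:
    """Prediction table (message_id, impact prob/flag, per-dimension prob/flag).

    Absent dimension probabilities (gated-out messages) serialize as empty
    cells. Probabilities are rounded to 6 decimals for stable files.
    """
    rows = []
    for p in predictions:
        row: dict = {
            "message_id": p.message_id,
            "impact_prob": round(p.impact_prob, 6),
            "impact_flag": int(p.impact_flag),
        }
        for d in DIMENSIONS:
            prob = p.dimension_probs.get(d)
            row[f"{d}_prob"] = round(prob, 6) if prob is not None else ""
            row[f"{d}_flag"] = int(p.dimension_flags.get(d, False))
        rows.append(row)
    cols = ["message_id", "impact_prob", "impact_flag"] + [
        f"{d}_{kind}" for d in DIMENSIONS for kind in ("prob", "flag")
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: HierarchicalModel, path: str | Path) -> None:
    """Write a model directory: model.json (provenance, thresholds, selected
    features, normalization state), lexicons.json, and one fitted-learner
    blob per stage."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "threshold": model.threshold,
        "seed": model.seed,
        "feature_names": model.feature_names,
        "provenance": model.provenance,
        "normalization": {
            "fitted_on": model.normalization.fitted_on,
            "max": model.normalization.max,
            "median": model.normalization.median,
        },
        "impact": {
            "selected": model.impact_model.selected,
            "best_params": model.impact_model.best_params,
            "cv_score": model.impact_model.cv_score,
        },
        "dimensions": {
            d: {
                "selected": m.selected,
                "best_params": m.best_params,
                "cv_score": None if np.isnan(m.cv_score) else m.cv_score,
                "untrainable": m.untrainable,
            }
            for d, m in model.dimension_models.items()
        },
    }
    with open(path / "model.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    save_lexicons(model.lexset, path / "lexicons.json")
    joblib.dump(model.impact_model.estimator, path / "impact.joblib")
    for d, m in model.dimension_models.items():
        if not m.untrainable:
            joblib.dump(m.estimator, path / f"{d}.joblib")


def load_model(path: str | Path) -> HierarchicalModel:
    path = Path(path)
    with open(path / "model.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    norm = NormalizationState(
        max=meta["normalization"]["max"],
        median=meta["normalization"]["median"],
        fitted_on=meta["normalization"].get("fitted_on", ""),
    )
    impact = DimensionModel(
        name="impact",
        estimator=joblib.load(path / "impact.joblib"),
        selected=meta["impact"]["selected"],
        best_params=meta["impact"]["best_params"],
        cv_score=meta["impact"]["cv_score"],
    )
    dims = {}
    for d, info in meta["dimensions"].items():
        if info["untrainable"]:
            dims[d] = DimensionModel(
                name=d, estimator=None, selected=[], best_params={},
                cv_score=float("nan"), untrainable=True,
            )
        else:
            dims[d] = DimensionModel(
                name=d,
                estimator=joblib.load(path / f"{d}.joblib"),
                selected=info["selected"],
                best_params=info["best_params"],
                cv_score=info["cv_score"],
            )
    return HierarchicalModel(
        impact_model=impact,
        dimension_models=dims,
        normalization=norm,
        lexset=load_lexicons(path / "lexicons.json"),
        threshold=meta["threshold"],
        feature_names=meta["feature_names"],
        config=TrainingConfig(threshold=meta["threshold"]),
        seed=meta["seed"],
        provenance=meta["provenance"],
    )
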