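"""Performance metrics and the learner-comparison harness.

Metrics follow the screening-test vocabulary: sensitivity (true positive
rate — correctly flagging an impacted message), specificity (true negative
rate), the F-measure, and the ROC curve with its AUC. AUC is computed as the
Mann–Whitney pair statistic (probability a random positive outscores a
random negative, ties counting one half), which equals the trapezoidal
integral of the ROC curve.

Dimension-level evaluation of the gated hierarchical model counts gated-out
messages (stage 1 negative) as negative dimension predictions with score 0,
reflecting end-to-end behavior as a user sees it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .annotation import AnnotationLabel
from .corpus_io import Corpus
from .lexicons import DIMENSIONS
from .modeling import (
    FAMILIES,
    HierarchicalModel,
    LearnerSpec,
    decision_scores,
    make_learner,
    predict,
)

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "UndefinedMetricError",
    "confusion",
    "sensitivity",
    "specificity",
    "f_measure",
    "roc_auc",
    "benchmark_learners",
    "evaluate_model",
    "TargetReport",
    "EvaluationReport",
    "save_report",
]


class UndefinedMetricError(ZeroDivisionError):
    """A rate metric's denominator is zero."""

    def __init__(self, metric: str, detail: str = ""):
        super().__init__(f"{metric} is undefined{': ' + detail if detail else ''}")
        self.metric = metric


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """tp / (tp + fn): the rate at which real impacts are caught."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity", "no positive ground-truth cases")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """tn / (tn + fp): the rate at which non-impacts are correctly passed."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity", "no negative ground-truth cases")
    return cm.tn / (cm.tn + cm.fp)


def f_measure(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("precision", "no positive predictions")
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("recall", "no positive ground-truth cases")
    precision = cm.tp / (cm.tp + cm.fp)
    recall = cm.tp / (cm.tp + cm.fn)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class RocCurve:
    """ROC points (fpr, tpr, threshold) from (0,0) to (1,1), plus the AUC."""

    points: list[tuple[float, float, float]]
    auc: float


def roc_auc(y_true: Sequence, scores: Sequence) -> RocCurve:
    """ROC curve and AUC for continuous scores.

    The AUC is the Mann–Whitney statistic: over all positive/negative pairs,
    the fraction where the positive outscores the negative, ties counting
    1/2. The curve sweeps the distinct score values as thresholds; its
    trapezoidal integral equals the pair statistic.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    ranks = rankdata(s)  # average ranks handle ties as 1/2
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    points: list[tuple[float, float, float]] = [(0.0, 0.0, float("inf"))]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        thr = s_sorted[i]
        while i < n and s_sorted[i] == thr:
            if y_sorted[i]:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg, tp / n_pos, float(thr)))
    if points[-1][:2] != (1.0, 1.0):
        points.append((1.0, 1.0, -float("inf")))
    return RocCurve(points=points, auc=float(auc))


def benchmark_learners(
    X,
    y: Sequence,
    families: Optional[list[LearnerSpec]] = None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired cross-validated AUC comparison of learner families.

    The same stratified folds are reused across families, so differences are
    paired. Returns one row per family with fold-level AUCs and the mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if families is None:
        families = [LearnerSpec(f) for f in FAMILIES]
    for spec in families:
        if spec.family not in FAMILIES:
            raise ValueError(f"unknown learner family {spec.family!r}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_indices = list(skf.split(X, y))
    rows = []
    for spec in families:
        fold_aucs = []
        for tr, va in fold_indices:
            est = make_learner(spec, seed=seed)
            est.fit(X[tr], y[tr])
            fold_aucs.append(roc_auc(y[va].astype(bool), decision_scores(est, X[va])).auc)
        row = {"family": spec.family, "mean_auc": float(np.mean(fold_aucs))}
        for i, a in enumerate(fold_aucs):
            row[f"fold_{i}"] = a
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TargetReport:
    """Metrics for one prediction target (impact or a dimension)."""

    target: str
    cm: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    f_measure: Optional[float]
    roc: Optional[RocCurve]

    @property
    def auc(self) -> Optional[float]:
        return self.roc.auc if self.roc is not None else None


@dataclass
class EvaluationReport:
    targets: dict[str, TargetReport]
    n: int


def _safe(metric_fn, cm: ConfusionMatrix) -> Optional[float]:
    try:
        return metric_fn(cm)
    except UndefinedMetricError:
        return None


def evaluate_model(
    model: HierarchicalModel, corpus: Corpus, labels: Iterable[AnnotationLabel]
) -> EvaluationReport:
    """End-to-end evaluation of a hierarchical model against gold labels.

    Every labeled message in the corpus is scored. For dimensions, gated-out
    messages (stage 1 negative) count as negative predictions with score 0.
    Undefined metrics (e.g. a dimension with no gold positives) are reported
    as None rather than raised.
    """
    by_id = {lab.message_id: lab for lab in labels}
    eval_ids = [m.id for m in corpus if m.id in by_id]
    if not eval_ids:
        raise ValueError("no overlap between corpus ids and label table")
    sub = Corpus([m for m in corpus if m.id in by_id], provenance=corpus.provenance)
    preds = {p.message_id: p for p in predict(model, sub)}

    targets: dict[str, TargetReport] = {}
    names = ["impact"] + list(DIMENSIONS)
    for name in names:
        if name == "impact":
            y_true = np.array([by_id[i].impact for i in eval_ids], dtype=bool)
            y_pred = np.array([preds[i].impact_flag for i in eval_ids], dtype=bool)
            scores = np.array([preds[i].impact_prob for i in eval_ids])
        else:
            y_true = np.array([by_id[i].dimensions.get(name, False) for i in eval_ids], dtype=bool)
            y_pred = np.array(
                [preds[i].dimension_flags.get(name, False) for i in eval_ids], dtype=bool
            )
            scores = np.array([preds[i].dimension_probs.get(name, 0.0) for i in eval_ids])
        cm = confusion(y_true, y_pred)
        roc = roc_auc(y_true, scores) if 0 < y_true.sum() < len(y_true) else None
        targets[name] = TargetReport(
            target=name,
            cm=cm,
            sensitivity=_safe(sensitivity, cm),
            specificity=_safe(specificity, cm),
            f_measure=_safe(f_measure, cm),
            roc=roc,
        )
    return EvaluationReport(targets=targets, n=len(eval_ids))


def save_report(report: EvaluationReport, out_dir: str | Path) -> None:
    """Write metrics.csv, per-target roc_<target>.csv, and metrics.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, tr in report.targets.items():
        rows.append(
            {
                "target": name,
                "tp": tr.cm.tp,
                "fp": tr.cm.fp,
                "tn": tr.cm.tn,
                "fn": tr.cm.fn,
                "sensitivity": tr.sensitivity,
                "specificity": tr.specificity,
                "f_measure": tr.f_measure,
                "auc": tr.auc,
            }
        )
        if tr.roc is not None:
            pd.DataFrame(tr.roc.points, columns=["fpr", "tpr", "threshold"]).to_csv(
                out_dir / f"roc_{name}.csv", index=False
            )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out_dir / "metrics.csv", index=False)
    with open(out_dir / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"n": report.n, "targets": metrics.set_index("target").to_dict(orient="index")},
            fh,
            indent=1,
            default=float,
        )
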