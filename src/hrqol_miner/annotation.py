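"""Gold-label schema and inter-annotator agreement.

Annotation is two-step: a message is first labeled *impacted* or *not
impacted* (any effect of disease/treatment on quality of life); if impacted,
the concerned dimensions among the five HRQoL dimensions are flagged and the
patient expressions conveying each impact are captured as character spans.
Agreement between two annotators on a doubly-annotated subset is summarized
by Cohen's kappa per label, with the convention that a degenerate table
(both raters constant and identical — e.g. a dimension never mentioned in
the subset) scores kappa = 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus_io import Corpus
from .lexicons import DIMENSIONS

__all__ = [
    "ExpressionSpan",
    "AnnotationLabel",
    "ValidationReport",
    "AgreementReport",
    "load_labels",
    "save_labels",
    "validate_labels",
    "cohen_kappa",
    "agreement_report",
]

LABEL_NAMES = ("impact",) + DIMENSIONS


@dataclass(frozen=True)
class ExpressionSpan:
    """A captured patient expression: [start, end) into normalized text."""

    start: int
    end: int
    dimension: str


@dataclass
class AnnotationLabel:
    """Gold labels for one message: overall impact + five dimension flags."""

    message_id: str
    impact: bool
    dimensions: dict[str, bool] = field(default_factory=lambda: {d: False for d in DIMENSIONS})
    expressions: list[ExpressionSpan] = field(default_factory=list)
    annotator: str = "unknown"


@dataclass
class ValidationReport:
    n_checked: int
    violations: list[str]
    n_unknown_ids: int = 0

    @property
    def passed(self) -> bool:
        return not self.violations


@dataclass
class AgreementReport:
    """Per-label Cohen kappa over a doubly-annotated message subset."""

    n: int
    kappa: dict[str, float]
    observed: dict[str, float]
    expected: dict[str, float]


def load_labels(path: str | Path, spans_path: Optional[str | Path] = None) -> list[AnnotationLabel]:
    """Read a label table CSV (message_id, annotator, impact, five dimensions).

    Boolean columns accept 0/1, true/false. An optional spans CSV
    (message_id, start, end, dimension) attaches captured expressions.
    """

    def as_bool(v: str) -> bool:
        return str(v).strip().lower() in {"1", "true", "yes"}

    labels: dict[tuple[str, str], AnnotationLabel] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            label = AnnotationLabel(
                message_id=row["message_id"],
                impact=as_bool(row["impact"]),
                dimensions={d: as_bool(row[d]) for d in DIMENSIONS},
                annotator=row.get("annotator") or "unknown",
            )
            labels[(label.message_id, label.annotator)] = label
    if spans_path is not None:
        by_id: dict[str, list[AnnotationLabel]] = {}
        for label in labels.values():
            by_id.setdefault(label.message_id, []).append(label)
        with open(spans_path, encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                span = ExpressionSpan(int(row["start"]), int(row["end"]), row["dimension"])
                for label in by_id.get(row["message_id"], []):
                    label.expressions.append(span)
    return list(labels.values())


def save_labels(
    labels: Iterable[AnnotationLabel],
    path: str | Path,
    spans_path: Optional[str | Path] = None,
) -> None:
    labels = list(labels)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["message_id", "annotator", "impact", *DIMENSIONS])
        for lab in labels:
            writer.writerow(
                [lab.message_id, lab.annotator, int(lab.impact)]
                + [int(lab.dimensions[d]) for d in DIMENSIONS]
            )
    if spans_path is not None:
        with open(spans_path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["message_id", "start", "end", "dimension"])
            for lab in labels:
                for span in lab.expressions:
                    writer.writerow([lab.message_id, span.start, span.end, span.dimension])


def validate_labels(labels: Iterable[AnnotationLabel], corpus: Corpus) -> ValidationReport:
    """Check label-table invariants against a corpus.

    Violations flagged: dimension flag set while impact is false; expression
    span outside the message text or tagged with an unflagged dimension.
    Labels referencing unknown message ids are reported but not fatal.
    """
    by_id = {m.id: m for m in corpus}
    violations: list[str] = []
    n_unknown = 0
    n = 0
    for lab in labels:
        n += 1
        msg = by_id.get(lab.message_id)
        if msg is None:
            n_unknown += 1
            violations.append(f"{lab.message_id}: unknown message id")
            continue
        if not lab.impact and any(lab.dimensions.get(d, False) for d in DIMENSIONS):
            violations.append(f"{lab.message_id}: dimension flagged but impact is false")
        for span in lab.expressions:
            if not (0 <= span.start < span.end <= len(msg.text)):
                violations.append(
                    f"{lab.message_id}: span [{span.start},{span.end}) outside text "
                    f"of length {len(msg.text)}"
                )
            if span.dimension not in DIMENSIONS:
                violations.append(f"{lab.message_id}: unknown span dimension {span.dimension!r}")
            elif not lab.dimensions.get(span.dimension, False):
                violations.append(
                    f"{lab.message_id}: span tagged {span.dimension} but flag is false"
                )
    return ValidationReport(n_checked=n, violations=violations, n_unknown_ids=n_unknown)


def cohen_kappa(a: Sequence[bool], b: Sequence[bool]) -> float:
    """Cohen's kappa for two binary raters from the 2x2 agreement table.

    kappa = (po - pe) / (1 - pe), with po the observed agreement rate and pe
    the chance agreement from the marginals. When pe = 1 (both raters constant
    and identical, including the all-negative case) kappa is 0 by convention.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"rating vectors must be equal-length 1-d, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("rating vectors must be non-empty")
    n = a.size
    po = float(np.mean(a == b))
    pa, pb = float(np.mean(a)), float(np.mean(b))
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def _kappa_parts(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    po = float(np.mean(a == b))
    pa, pb = float(np.mean(a)), float(np.mean(b))
    pe = pa * pb + (1 - pa) * (1 - pb)
    kappa = 0.0 if pe >= 1.0 else (po - pe) / (1 - pe)
    return kappa, po, pe


def agreement_report(
    labels_a: Iterable[AnnotationLabel], labels_b: Iterable[AnnotationLabel]
) -> AgreementReport:
    """Per-label kappa between two annotators over the same message set."""
    map_a = {lab.message_id: lab for lab in labels_a}
    map_b = {lab.message_id: lab for lab in labels_b}
    if set(map_a) != set(map_b):
        diff = sorted(set(map_a) ^ set(map_b))
        raise ValueError(f"label tables cover different message ids: {diff}")
    ids = sorted(map_a)
    if not ids:
        raise ValueError("label tables are empty")

    def vec(labels: dict[str, AnnotationLabel], name: str) -> np.ndarray:
        if name == "impact":
            return np.array([labels[i].impact for i in ids], dtype=bool)
        return np.array([labels[i].dimensions.get(name, False) for i in ids], dtype=bool)

    kappa, observed, expected = {}, {}, {}
    for name in LABEL_NAMES:
        k, po, pe = _kappa_parts(vec(map_a, name), vec(map_b, name))
        kappa[name], observed[name], expected[name] = k, po, pe
    return AgreementReport(n=len(ids), kappa=kappa, observed=observed, expected=expected)
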