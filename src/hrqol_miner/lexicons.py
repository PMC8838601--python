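"""Expression lists driving lexical-field and sentiment features.

Two kinds of lexicons are used. *Dimension* lexicons hold patient expressions
of an impact on one of the five HRQoL dimensions (physical, psychic,
activity, relational, financial), harvested during annotation. *Sentiment*
lexicons hold word lists for eight affect categories (positive, negative,
anger, disgust, fear, joy, sadness, surprise), in the tradition of
psycholinguistic word-count dictionaries. The package bundles small open
French fixture lexicons of both kinds; the JSON file format keeps them
swappable for a licensed sentiment dictionary export of the same shape.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .corpus_io import Corpus, normalize_text

logger = logging.getLogger(__name__)

__all__ = [
    "DIMENSIONS",
    "SENTIMENTS",
    "Lexicon",
    "LexiconSet",
    "LexiconValidationError",
    "load_lexicons",
    "save_lexicons",
    "bundled_lexicons",
    "build_lexicon_from_annotations",
]

#: The five HRQoL impact dimensions, in canonical order.
DIMENSIONS = ("physical", "psychic", "activity", "relational", "financial")

#: The eight sentiment categories, in canonical order.
SENTIMENTS = (
    "positive",
    "negative",
    "anger",
    "disgust",
    "fear",
    "joy",
    "sadness",
    "surprise",
)


class LexiconValidationError(ValueError):
    """A lexicon file or expression violates the lexicon contract."""


@dataclass(frozen=True)
class Lexicon:
    """A named set of normalized expressions (single- or multi-word)."""

    name: str
    expressions: frozenset[str]
    language: str = "fr"

    def __len__(self) -> int:
        return len(self.expressions)

    def __contains__(self, expression: str) -> bool:
        return expression in self.expressions


@dataclass
class LexiconSet:
    """Mapping from lexicon name to :class:`Lexicon`.

    A *complete* set carries all five dimension lexicons and all eight
    sentiment lexicons; feature extraction requires completeness.
    """

    lexicons: dict[str, Lexicon] = field(default_factory=dict)
    version: str = "0"

    def __getitem__(self, name: str) -> Lexicon:
        return self.lexicons[name]

    def __contains__(self, name: str) -> bool:
        return name in self.lexicons

    def missing(self) -> list[str]:
        required = list(DIMENSIONS) + list(SENTIMENTS)
        return [name for name in required if name not in self.lexicons]

    def is_complete(self) -> bool:
        return not self.missing()


def _make_lexicon(name: str, expressions: Iterable[str], language: str = "fr") -> Lexicon:
    normalized = set()
    for expr in expressions:
        norm = normalize_text(expr)
        if not norm:
            raise LexiconValidationError(
                f"lexicon {name!r} contains an empty expression ({expr!r})"
            )
        normalized.add(norm)
    return Lexicon(name=name, expressions=frozenset(normalized), language=language)


def load_lexicons(path: str | Path, version: Optional[str] = None) -> LexiconSet:
    """Load a JSON file mapping lexicon names to expression arrays.

    Expressions are normalized with the corpus text rules, duplicates
    collapse, and an unknown lexicon name is kept under its given name with
    a warning. A completeness report is logged.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise LexiconValidationError(f"{path.name}: expected a JSON object at top level")
    known = set(DIMENSIONS) | set(SENTIMENTS)
    lexicons = {}
    for name, expressions in data.items():
        if name not in known:
            logger.warning("load_lexicons: unknown lexicon name %r (kept)", name)
        lexicons[name] = _make_lexicon(name, expressions)
    lexset = LexiconSet(lexicons=lexicons, version=version or path.stem)
    if lexset.is_complete():
        logger.info("load_lexicons(%s): complete set (%d lexicons)", path.name, len(lexicons))
    else:
        logger.info("load_lexicons(%s): missing %s", path.name, lexset.missing())
    return lexset


def save_lexicons(lexset: LexiconSet, path: str | Path) -> None:
    """Serialize as JSON {name: sorted expression list} (round-trips)."""
    data = {name: sorted(lex.expressions) for name, lex in lexset.lexicons.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, ensure_ascii=False, indent=1)


def bundled_lexicons() -> LexiconSet:
    """The packaged open French fixture lexicons (complete set)."""
    ref = resources.files("hrqol_miner.data").joinpath("lexicons_fr.json")
    with resources.as_file(ref) as path:
        return load_lexicons(path, version="bundled-fr")


def build_lexicon_from_annotations(
    labels: Iterable,
    corpus: Corpus,
    dimension: str,
    min_count: int = 1,
) -> Lexicon:
    """Harvest annotated expressions of one dimension into a lexicon.

    Every expression span tagged with ``dimension`` across the label table is
    materialized from the message text and normalized; expressions occurring
    at least ``min_count`` times are retained. A dimension with no captured
    spans yields an empty lexicon. Deterministic, and monotone non-increasing
    in ``min_count``.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    counts: Counter[str] = Counter()
    by_id = {m.id: m for m in corpus}
    for label in labels:
        msg = by_id.get(label.message_id)
        if msg is None:
            continue
        for span in label.expressions:
            if span.dimension != dimension:
                continue
            surface = normalize_text(msg.text[span.start : span.end])
            if surface:
                counts[surface] += 1
    kept = frozenset(e for e, c in counts.items() if c >= min_count)
    return Lexicon(name=dimension, expressions=kept)
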