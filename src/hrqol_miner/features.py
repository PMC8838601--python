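"""Quantitative feature engineering for forum messages.

Each message is mapped to a fixed 25-feature vector:

* five lexical-field scores (``lex_<dimension>``) — counts of dimension
  lexicon expressions in the text;
* eight sentiment counts (``sent_<category>``) — same counting rule on the
  sentiment lexicons;
* grammar counts — pronouns, first-person singular/plural markers ("who is
  writing"), French negation constructions, and the bare negator "pas";
* conjugation counts — infinitives, present-tense and imparfait finite
  verbs, past participles;
* structure — characters, tokens, sentences.

Lexical counting is token-boundary anchored, non-overlapping and
leftmost-longest (a text containing "mal au dos" scores once for a lexicon
holding both "mal" and "mal au dos"). Normalization divides every feature by
its training maximum after median imputation, so all modeling inputs lie in
[0, 1]; applying a fitted state to unseen data clips back into that range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .corpus_io import Corpus, split_sentences
from .lexicons import DIMENSIONS, SENTIMENTS, Lexicon, LexiconSet
from .tagger import MorphTag, Tagger, tag_morphology
from .term_matching import tokenize_with_spans

__all__ = [
    "FEATURE_NAMES",
    "LEXICAL_FEATURES",
    "SENTIMENT_FEATURES",
    "ConfigurationError",
    "NormalizationState",
    "lexical_field_score",
    "sentiment_counts",
    "negation_count",
    "not_count",
    "extract_features",
    "fit_normalization",
    "apply_normalization",
]


class ConfigurationError(ValueError):
    """Feature extraction was configured with incomplete resources."""


LEXICAL_FEATURES = [f"lex_{d}" for d in DIMENSIONS]
SENTIMENT_FEATURES = [f"sent_{s}" for s in SENTIMENTS]
GRAMMAR_FEATURES = ["n_pronouns", "n_first_singular", "n_first_plural", "n_negations", "n_not_tokens"]
CONJUGATION_FEATURES = ["n_infinitive", "n_present", "n_past", "n_past_participle"]
STRUCTURE_FEATURES = ["n_chars", "n_tokens", "n_sentences"]

#: Fixed, documented feature inventory (column order of every matrix).
FEATURE_NAMES = (
    LEXICAL_FEATURES
    + SENTIMENT_FEATURES
    + GRAMMAR_FEATURES
    + CONJUGATION_FEATURES
    + STRUCTURE_FEATURES
)


def _tokens(text: str) -> list[str]:
    return [t for t, _, _ in tokenize_with_spans(text)]


def lexical_field_score(text: str, lexicon: Lexicon) -> int:
    """Count non-overlapping occurrences of lexicon expressions in the text.

    Matching is over the token sequence: a multi-word expression matches a
    contiguous run of tokens. At each position the longest matching
    expression wins and consumes its tokens (leftmost-longest).
    """
    tokens = _tokens(text)
    if not tokens or not lexicon.expressions:
        return 0
    expr_tokens = sorted(
        (tuple(_tokens(e)) for e in lexicon.expressions if _tokens(e)),
        key=len,
        reverse=True,
    )
    count = 0
    i = 0
    n = len(tokens)
    while i < n:
        matched = 0
        for expr in expr_tokens:
            k = len(expr)
            if i + k <= n and tuple(tokens[i : i + k]) == expr:
                matched = k
                break
        if matched:
            count += 1
            i += matched
        else:
            i += 1
    return count


def sentiment_counts(text: str, lexset: LexiconSet) -> dict[str, int]:
    """Per-category expression counts over the eight sentiment lexicons.

    Categories are independent: a word listed in two categories counts in
    both.
    """
    return {s: lexical_field_score(text, lexset[s]) for s in SENTIMENTS}


_NEGATORS = ("pas", "plus", "jamais", "rien", "personne", "aucun", "aucune")
_NEG_WINDOW = 5  # max tokens between "ne/n'" and its negator


def negation_count(tags: list[MorphTag]) -> int:
    """Count French negation constructions in a tagged token sequence.

    A ``ne``/``n'`` followed within a few tokens by a negator
    (pas/plus/jamais/rien/...) counts once and consumes that negator; any
    remaining bare ``pas`` counts once each.
    """
    tokens = [t.token.lower() for t in tags]
    consumed = [False] * len(tokens)
    count = 0
    for i, tok in enumerate(tokens):
        if tok in {"ne", "n"}:
            for j in range(i + 1, min(i + 1 + _NEG_WINDOW, len(tokens))):
                if not consumed[j] and tokens[j] in _NEGATORS:
                    consumed[j] = True
                    count += 1
                    break
    for j, tok in enumerate(tokens):
        if tok == "pas" and not consumed[j]:
            count += 1
    return count


def not_count(tags: list[MorphTag]) -> int:
    """Occurrences of the bare negator token "pas" (the French "not")."""
    return sum(1 for t in tags if t.token.lower() == "pas")


def _message_features(text: str, lexset: LexiconSet, tagger: Optional[Tagger]) -> dict[str, float]:
    tokens = _tokens(text)
    tags = tag_morphology(tokens, tagger)
    feats: dict[str, float] = {}
    for d in DIMENSIONS:
        feats[f"lex_{d}"] = lexical_field_score(text, lexset[d])
    for s, c in sentiment_counts(text, lexset).items():
        feats[f"sent_{s}"] = c
    feats["n_pronouns"] = sum(1 for t in tags if t.pos == "pronoun")
    feats["n_first_singular"] = sum(1 for t in tags if t.pos == "pronoun" and t.person == "1sg")
    feats["n_first_plural"] = sum(1 for t in tags if t.pos == "pronoun" and t.person == "1pl")
    feats["n_negations"] = negation_count(tags)
    feats["n_not_tokens"] = not_count(tags)
    feats["n_infinitive"] = sum(1 for t in tags if t.form == "infinitive")
    feats["n_present"] = sum(1 for t in tags if t.tense == "present" and t.form == "finite")
    feats["n_past"] = sum(1 for t in tags if t.tense == "past" and t.form == "finite")
    feats["n_past_participle"] = sum(1 for t in tags if t.form == "past_participle")
    feats["n_chars"] = len(text)
    feats["n_tokens"] = len(tokens)
    feats["n_sentences"] = len(split_sentences(text))
    return feats


def extract_features(
    corpus: Corpus, lexset: LexiconSet, tagger: Optional[Tagger] = None
) -> pd.DataFrame:
    """Build the raw feature matrix (rows = messages, columns = FEATURE_NAMES).

    Requires a complete lexicon set (five dimensions + eight sentiment
    categories). Deterministic: identical corpus, lexicons and tagger yield an
    identical matrix. The row index is the message id, in corpus order.
    """
    if not lexset.is_complete():
        raise ConfigurationError(f"incomplete lexicon set; missing {lexset.missing()}")
    rows = [_message_features(m.text, lexset, tagger) for m in corpus]
    df = pd.DataFrame(rows, index=pd.Index(corpus.ids(), name="message_id"), dtype=float)
    return df[FEATURE_NAMES]


@dataclass
class NormalizationState:
    """Per-feature training maximum and median (fit on training data only)."""

    max: dict[str, float]
    median: dict[str, float]
    fitted_on: str = ""

    def to_json(self, path: str | Path) -> None:
        data = {
            "fitted_on": self.fitted_on,
            "features": {
                name: {"max": self.max[name], "median": self.median[name]} for name in self.max
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationState":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        feats = data["features"]
        return cls(
            max={k: v["max"] for k, v in feats.items()},
            median={k: v["median"] for k, v in feats.items()},
            fitted_on=data.get("fitted_on", ""),
        )


def fit_normalization(train: pd.DataFrame, fitted_on: str = "") -> NormalizationState:
    """Fit per-feature median (for imputation) and maximum (for scaling)."""
    if train.empty:
        raise ValueError("cannot fit normalization on an empty matrix")
    median = train.median(axis=0, skipna=True).fillna(0.0)
    maximum = train.fillna(median).max(axis=0).fillna(0.0)
    return NormalizationState(
        max={k: float(v) for k, v in maximum.items()},
        median={k: float(v) for k, v in median.items()},
        fitted_on=fitted_on,
    )


def apply_normalization(matrix: pd.DataFrame, state: NormalizationState) -> pd.DataFrame:
    """Impute with the training median, scale by the training max, clip to [0,1].

    Features with a training maximum of 0 map to 0. Unseen data may exceed
    the training maximum; values are clipped back into [0, 1].
    """
    missing = [c for c in matrix.columns if c not in state.max]
    if missing:
        raise ValueError(f"features absent from normalization state: {missing}")
    out = matrix.copy()
    for col in out.columns:
        med, mx = state.median[col], state.max[col]
        out[col] = out[col].fillna(med)
        out[col] = out[col] / mx if mx > 0 else 0.0
    return out.clip(lower=0.0, upper=1.0)
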