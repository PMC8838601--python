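"""Dictionary-driven recognition of drug and disease mentions.

Health-related messages are selected by a small NER-style module: a term
dictionary (surface form, canonical form, drug/disease category) is scanned
against each message, either exactly or approximately. Approximate matching
is token-boundary anchored and uses a length-scaled Levenshtein budget —
short surfaces (<5 chars) must match exactly, medium surfaces (5–9 chars)
tolerate one edit, long surfaces (≥10 chars) up to two — which keeps short
drug names from matching everywhere while still catching the common
misspellings of long brand names.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .corpus_io import Corpus, normalize_text

__all__ = [
    "TermEntry",
    "TermDictionary",
    "TermMention",
    "load_dictionary",
    "match_terms",
    "filter_health_related",
    "mentions_to_frame",
    "levenshtein",
    "tokenize_with_spans",
]

CATEGORIES = ("drug", "disease")


@dataclass(frozen=True)
class TermEntry:
    surface: str  # normalized surface form
    canonical: str
    category: str  # "drug" | "disease"


@dataclass
class TermDictionary:
    """Named list of drug/disease surface forms (surfaces pre-normalized)."""

    name: str
    entries: list[TermEntry]
    match_mode: str = "exact"  # "exact" | "approximate"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"term dictionary {self.name!r} has no entries")
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"unknown term category {e.category!r}")

    def surfaces(self) -> list[str]:
        return [e.surface for e in self.entries]


@dataclass(frozen=True)
class TermMention:
    """One dictionary hit in a message's normalized text."""

    message_id: str
    start: int
    end: int  # half-open [start, end)
    surface: str  # matched substring of the text
    canonical: str
    category: str
    edit_distance: int


def load_dictionary(
    path: str | Path, name: Optional[str] = None, match_mode: str = "exact"
) -> TermDictionary:
    """Read a CSV dictionary with columns surface, canonical, category."""
    path = Path(path)
    entries = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            surface = normalize_text(row["surface"])
            if not surface:
                continue
            entries.append(
                TermEntry(
                    surface=surface,
                    canonical=row.get("canonical") or surface,
                    category=row["category"].strip().lower(),
                )
            )
    return TermDictionary(name=name or path.stem, entries=entries, match_mode=match_mode)


_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


def tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    """Word tokens with [start, end) character offsets (``\\w+`` runs)."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def levenshtein(a: str, b: str) -> int:
    """Plain edit distance (insert/delete/substitute, unit costs)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def allowed_distance(surface: str, max_distance: int) -> int:
    """Length-scaled edit budget: 0 below 5 chars, ≤1 at 5–9, ≤2 at ≥10."""
    n = len(surface)
    if n < 5:
        return 0
    if n < 10:
        return min(max_distance, 1)
    return min(max_distance, 2)


def match_terms(
    text: str,
    dictionary: TermDictionary,
    max_distance: int = 0,
    message_id: str = "",
) -> list[TermMention]:
    """Find dictionary mentions in normalized text.

    A surface of k tokens is compared against every window of k consecutive
    text tokens (window tokens joined by single spaces). Matching is anchored
    at token boundaries, so "rage" never matches inside "courage". Overlapping
    candidates are resolved leftmost-longest, then lowest edit distance.
    Mentions are returned in span order. In exact mode the edit budget is
    forced to zero.
    """
    if dictionary.match_mode == "exact":
        max_distance = 0
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")

    tokens = tokenize_with_spans(text)
    if not tokens:
        return []

    candidates: list[TermMention] = []
    for entry in dictionary.entries:
        surface_tokens = entry.surface.split(" ")
        k = len(surface_tokens)
        budget = allowed_distance(entry.surface, max_distance)
        for i in range(len(tokens) - k + 1):
            window = tokens[i : i + k]
            window_str = " ".join(t[0] for t in window)
            if abs(len(window_str) - len(entry.surface)) > budget:
                continue
            d = levenshtein(window_str, entry.surface)
            if d <= budget:
                start, end = window[0][1], window[-1][2]
                candidates.append(
                    TermMention(
                        message_id=message_id,
                        start=start,
                        end=end,
                        surface=text[start:end],
                        canonical=entry.canonical,
                        category=entry.category,
                        edit_distance=d,
                    )
                )

    # leftmost-longest, then lowest distance; greedy non-overlapping selection
    candidates.sort(key=lambda m: (m.start, -m.end, m.edit_distance, m.canonical))
    selected: list[TermMention] = []
    last_end = -1
    for cand in candidates:
        if cand.start >= last_end:
            selected.append(cand)
            last_end = cand.end
    return selected


def filter_health_related(
    corpus: Corpus, dictionary: TermDictionary, max_distance: int = 0
) -> tuple[Corpus, pd.DataFrame]:
    """Keep only messages with at least one dictionary mention.

    Returns the filtered sub-corpus (original order preserved) and the full
    mention table for the whole input corpus.
    """
    mentions: list[TermMention] = []
    keep_ids = set()
    for m in corpus:
        hits = match_terms(m.text, dictionary, max_distance=max_distance, message_id=m.id)
        if hits:
            keep_ids.add(m.id)
            mentions.extend(hits)
    kept = Corpus(
        [m for m in corpus if m.id in keep_ids],
        provenance=corpus.provenance + " | health-term filtered",
    )
    return kept, mentions_to_frame(mentions)


def mentions_to_frame(mentions: Iterable[TermMention]) -> pd.DataFrame:
    """Mention table as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "message_id": m.message_id,
                "start": m.start,
                "end": m.end,
                "surface": m.surface,
                "canonical": m.canonical,
                "category": m.category,
                "edit_distance": m.edit_distance,
            }
            for m in mentions
        ],
        columns=[
            "message_id",
            "start",
            "end",
            "surface",
            "canonical",
            "category",
            "edit_distance",
        ],
    )
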