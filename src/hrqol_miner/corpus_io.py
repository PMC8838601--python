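"""Corpus ingestion and preprocessing for patient forum messages.

A *corpus* is an ordered collection of forum posts. Preprocessing follows the
usual social-media-listening recipe: assign every message a stable identifier,
normalize the text (Unicode NFC, lowercasing, whitespace collapsing, HTML
entity decoding, URL tokenization), detect sentences with a rule-based
splitter, drop byte-identical duplicates, and split into training/validation
sets. All character offsets elsewhere in the package (term mentions, planted
expression spans, annotation spans) refer to the *normalized* text, 0-based,
half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import html
import json
import logging
import math
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Message",
    "Corpus",
    "SplitResult",
    "SchemaError",
    "load_corpus",
    "write_corpus",
    "normalize_text",
    "normalize_corpus",
    "deduplicate",
    "split_sentences",
    "split_corpus",
    "DEFAULT_ABBREVIATIONS",
]


class SchemaError(ValueError):
    """A corpus file violates the expected record schema."""


@dataclass(frozen=True)
class Message:
    """One forum post: the pipeline's atomic input."""

    id: str
    text: str
    source: str = "unknown"
    posted_at: Optional[str] = None  # ISO-8601 string or None
    language: str = "fr"


@dataclass
class Corpus:
    """Ordered collection of messages with unique ids (input order is stable)."""

    messages: list[Message]
    provenance: str = ""
    n_dropped: int = 0  # records removed at load/normalize time

    def __post_init__(self) -> None:
        ids = [m.id for m in self.messages]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate message id in corpus: {dup!r}")

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self) -> Iterator[Message]:
        return iter(self.messages)

    def ids(self) -> list[str]:
        return [m.id for m in self.messages]

    def get(self, message_id: str) -> Message:
        for m in self.messages:
            if m.id == message_id:
                return m
        raise KeyError(message_id)


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/validation partition of a corpus."""

    train: Corpus
    validation: Corpus
    ratio: float
    seed: int


_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_WS_RE = re.compile(r"\s+")

#: Sentence-final abbreviations that do not end a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {"dr.", "etc.", "m.", "mme.", "mlle.", "ex.", "cf.", "p.", "st.", "vs."}
)


def normalize_text(raw: str) -> str:
    """Canonicalize a raw message text.

    Applies, in order: HTML entity decoding, Unicode NFC normalization, URL
    replacement by the token ``<url>``, lowercasing, and whitespace collapsing
    with stripping. Accents are preserved. Total function: never raises.

    Entity decoding is applied once per call, so the function is idempotent on
    any text that does not itself contain encoded entities (e.g. a literal
    ``&amp;``).
    """
    text = html.unescape(raw)
    text = unicodedata.normalize("NFC", text)
    text = _URL_RE.sub("<url>", text)
    text = text.lower()
    text = _WS_RE.sub(" ", text).strip()
    return text


def _generated_id(stem: str, ordinal: int) -> str:
    return f"{stem}-{ordinal:06d}"


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".ndjson"}:
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer corpus format from {path.name!r}; pass format=")


def load_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a JSONL or CSV corpus file.

    Records lacking an ``id`` receive a deterministic generated id (the file
    stem followed by a zero-padded 1-based ordinal). Records whose ``text`` is
    empty or whitespace-only are dropped and counted in ``Corpus.n_dropped``.
    A record without a ``text`` field at all raises :class:`SchemaError`
    naming its index.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    stem = path.stem

    raw_records: list[dict]
    if fmt == "jsonl":
        raw_records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    raw_records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"line {lineno}: invalid JSON: {exc}") from exc
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            raw_records = list(csv.DictReader(fh))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")

    messages: list[Message] = []
    dropped = 0
    for i, rec in enumerate(raw_records):
        if "text" not in rec or rec["text"] is None:
            raise SchemaError(f"record {i} has no 'text' field")
        text = str(rec["text"])
        if not text.strip():
            dropped += 1
            continue
        msg_id = rec.get("id") or _generated_id(stem, i + 1)
        messages.append(
            Message(
                id=str(msg_id),
                text=text,
                source=str(rec.get("source") or "unknown"),
                posted_at=rec.get("posted_at") or None,
                language=str(rec.get("language") or "fr"),
            )
        )
    if dropped:
        logger.info("load_corpus(%s): dropped %d empty-text records", path.name, dropped)
    return Corpus(messages, provenance=f"loaded from {path.name}", n_dropped=dropped)


def write_corpus(corpus: Corpus, path: str | Path, format: Optional[str] = None) -> None:
    """Write a corpus as JSONL or CSV (round-trips with :func:`load_corpus`)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for m in corpus:
                rec = {"id": m.id, "text": m.text, "source": m.source}
                if m.posted_at is not None:
                    rec["posted_at"] = m.posted_at
                rec["language"] = m.language
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["id", "text", "source", "posted_at", "language"]
            )
            writer.writeheader()
            for m in corpus:
                writer.writerow(
                    {
                        "id": m.id,
                        "text": m.text,
                        "source": m.source,
                        "posted_at": m.posted_at or "",
                        "language": m.language,
                    }
                )
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


def normalize_corpus(corpus: Corpus) -> Corpus:
    """Apply :func:`normalize_text` to every message; drop texts that become empty."""
    messages = []
    dropped = 0
    for m in corpus:
        text = normalize_text(m.text)
        if not text:
            dropped += 1
            logger.info("normalize_corpus: dropping %s (empty after normalization)", m.id)
            continue
        messages.append(replace(m, text=text))
    return Corpus(
        messages,
        provenance=corpus.provenance + " | normalized",
        n_dropped=corpus.n_dropped + dropped,
    )


def deduplicate(corpus: Corpus) -> Corpus:
    """Remove messages whose normalized text is byte-identical to an earlier one.

    The first occurrence is kept; removal count is logged. Texts are expected
    to be normalized already (the key is exact string identity).
    """
    seen: set[str] = set()
    kept = []
    for m in corpus:
        if m.text in seen:
            continue
        seen.add(m.text)
        kept.append(m)
    removed = len(corpus) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d duplicate messages", removed)
    return Corpus(kept, provenance=corpus.provenance + " | deduplicated", n_dropped=corpus.n_dropped)


_SENT_PUNCT = ".!?…"


def split_sentences(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[str]:
    """Rule-based sentence detection on normalized text.

    A boundary is a sentence-final character (``. ! ? …``) followed by a space
    and a letter, unless the token ending at the punctuation is a known
    abbreviation (``dr.``, ``etc.``, ...). Joining the returned sentences with
    single spaces reconstructs the input text.
    """
    boundaries: list[int] = []
    for m in re.finditer(rf"[{re.escape(_SENT_PUNCT)}]", text):
        i = m.end()
        if i >= len(text) or text[i] != " ":
            continue
        if i + 1 >= len(text) or not text[i + 1].isalpha():
            continue
        word = text[: m.end()].rsplit(" ", 1)[-1]
        if word in abbreviations:
            continue
        boundaries.append(i)
    sentences = []
    start = 0
    for b in boundaries:
        sentences.append(text[start:b])
        start = b + 1  # skip the single separating space
    tail = text[start:]
    if tail:
        sentences.append(tail)
    return sentences


def split_corpus(corpus: Corpus, ratio: float, seed: int) -> SplitResult:
    """Uniform random train/validation partition.

    ``|train| = floor(ratio * n)`` — e.g. 1399 messages at ratio 0.70 give
    979 training and 420 validation messages. Input order is preserved within
    each part; the partition is deterministic given (corpus order, ratio, seed).
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    n = len(corpus)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    n_train = math.floor(ratio * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [m for i, m in enumerate(corpus) if i in train_idx]
    validation = [m for i, m in enumerate(corpus) if i not in train_idx]
    return SplitResult(
        train=Corpus(train, provenance=corpus.provenance + " | train split"),
        validation=Corpus(validation, provenance=corpus.provenance + " | validation split"),
        ratio=ratio,
        seed=seed,
    )
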