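"""Synthetic labeled forum corpora with known ground truth.

The generator emulates the statistical structure of a French patient-forum
corpus: message lengths follow a lognormal law matching a mean of 905
characters (SD 1041); a configurable fraction of messages mention an impact
on health-related quality of life (default 58%), with per-dimension
prevalences of 31/37/25/13/4 % for the physical, psychic, activity,
relational and financial dimensions; impacted messages are written in the
first person and carry planted dimension-lexicon expressions (Poisson count,
at least one per positive dimension); messages carry a drug/disease
dictionary term at a configurable rate. Filler sentences are neutral and
disjoint from the dimension lexicons and the term dictionary by
construction, so at zero noise the lexical-field score of a dimension equals
exactly the number of planted expressions.

Texts are emitted already normalized (lowercase, NFC, single spaces), so all
recorded spans index directly into the message text. The generator is fully
deterministic given its seed. It produces plausible statistical structure,
not linguistically realistic French.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationLabel, ExpressionSpan
from .corpus_io import Corpus, Message
from .lexicons import DIMENSIONS, LexiconSet, bundled_lexicons
from .term_matching import TermDictionary, load_dictionary

__all__ = [
    "GeneratorSpec",
    "SyntheticCorpus",
    "bundled_dictionary",
    "generate_corpus",
    "generate_feature_table",
    "DEFAULT_PREVALENCE",
]

#: Default per-label positive rates of the emulated annotated corpus.
DEFAULT_PREVALENCE: dict[str, float] = {
    "impact": 0.58,
    "physical": 0.31,
    "psychic": 0.37,
    "activity": 0.25,
    "relational": 0.13,
    "financial": 0.04,
}


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic corpus."""

    n: int = 1399
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    signal: float = 2.0  # expected planted expressions per positive dimension
    noise: float = 0.02  # rate of stray expressions for negative dimensions
    length_mean: float = 905.0  # mean message length, characters
    length_sd: float = 1041.0
    health_term_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        p_impact = self.prevalence["impact"]
        for name, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{name!r}] = {p} outside [0, 1]")
            if name != "impact" and p > p_impact:
                raise ValueError(
                    f"dimension prevalence {name}={p} exceeds impact prevalence {p_impact}"
                )


@dataclass
class SyntheticCorpus:
    """A generated corpus with gold labels and exact planted spans."""

    corpus: Corpus
    labels: list[AnnotationLabel]
    planted: dict[str, dict[str, list[tuple[int, int]]]]  # id -> dimension -> spans
    with_health_term: set[str]
    spec: GeneratorSpec


def bundled_dictionary(match_mode: str = "exact") -> TermDictionary:
    """The packaged fixture drug/disease dictionary."""
    ref = resources.files("hrqol_miner.data").joinpath("terms_fr.csv")
    with resources.as_file(ref) as path:
        return load_dictionary(path, name="bundled-fr", match_mode=match_mode)


def _bundled_fillers() -> list[str]:
    ref = resources.files("hrqol_miner.data").joinpath("fillers_fr.txt")
    text = ref.read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


_OPENERS = [
    "je voulais raconter un peu mon quotidien ici.",
    "je poste ce message après une longue hésitation.",
    "j'écris ici parce que tout est devenu compliqué.",
]

# each template holds one {e} slot for a planted expression
_EXPRESSION_TEMPLATES = [
    "j'ai {e} depuis plusieurs mois.",
    "je vis avec {e} au quotidien.",
    "en ce moment {e} me pèse énormément.",
    "cela provoque {e} presque tous les jours.",
    "je ne supporte plus {e} à la longue.",
]

_STRAY_TEMPLATES = [
    "une connaissance évoque parfois {e} dans son entourage.",
    "un autre membre décrivait {e} dans un ancien sujet.",
]

_TERM_TEMPLATES = [
    "le traitement {t} revient souvent dans les discussions.",
    "ce forum parle beaucoup de {t} en ce moment.",
    "plusieurs membres évoquent {t} dans leurs messages.",
    "la question de {t} revient régulièrement ici.",
]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_corpus(
    spec: Optional[GeneratorSpec] = None,
    lexset: Optional[LexiconSet] = None,
    dictionary: Optional[TermDictionary] = None,
) -> SyntheticCorpus:
    """Generate a labeled synthetic corpus under the given study conditions.

    Per message: impact is Bernoulli(prevalence.impact); given impact, each
    dimension is Bernoulli(prevalence.dim / prevalence.impact), redrawn until
    at least one dimension is positive; each positive dimension receives
    ``max(1, Poisson(signal))`` planted expressions from its lexicon; each
    negative dimension receives a stray expression with probability
    ``noise``; a dictionary term appears at rate ``health_term_rate``; filler
    sentences pad the message toward a lognormal length target. Byte-identical
    output for identical spec and seed.
    """
    spec = spec or GeneratorSpec()
    lexset = lexset or bundled_lexicons()
    dictionary = dictionary or bundled_dictionary()
    p_impact = spec.prevalence["impact"]
    for d in DIMENSIONS:
        if spec.prevalence.get(d, 0.0) > 0 and len(lexset[d]) == 0:
            raise ValueError(f"dimension {d} has prevalence > 0 but an empty lexicon")

    expressions = {d: sorted(lexset[d].expressions) for d in DIMENSIONS}
    surfaces = sorted({e.surface for e in dictionary.entries})
    fillers = _bundled_fillers()
    mu, sigma = _lognormal_params(spec.length_mean, spec.length_sd)
    rng = np.random.default_rng(spec.seed)

    messages: list[Message] = []
    labels: list[AnnotationLabel] = []
    planted_all: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with_term: set[str] = set()

    for i in range(spec.n):
        mid = f"synthetic-{i + 1:06d}"
        impact = bool(rng.random() < p_impact) if p_impact > 0 else False
        dims = {d: False for d in DIMENSIONS}
        if impact:
            while True:
                for d in DIMENSIONS:
                    p_cond = spec.prevalence.get(d, 0.0) / p_impact
                    dims[d] = bool(rng.random() < p_cond)
                if any(dims.values()):
                    break

        # parts: (sentence, [(local_start, local_end, dimension)]) — spans for planted only
        parts: list[tuple[str, list[tuple[int, int, str]]]] = []
        if impact:
            parts.append((_OPENERS[int(rng.integers(len(_OPENERS)))], []))
        if rng.random() < spec.health_term_rate:
            term = surfaces[int(rng.integers(len(surfaces)))]
            template = _TERM_TEMPLATES[int(rng.integers(len(_TERM_TEMPLATES)))]
            parts.append((template.format(t=term), []))
            with_term.add(mid)
        for d in DIMENSIONS:
            if dims[d]:
                count = max(1, int(rng.poisson(spec.signal)))
                for _ in range(count):
                    expr = expressions[d][int(rng.integers(len(expressions[d])))]
                    template = _EXPRESSION_TEMPLATES[int(rng.integers(len(_EXPRESSION_TEMPLATES)))]
                    local = template.index("{e}")
                    parts.append((template.format(e=expr), [(local, local + len(expr), d)]))
            elif spec.noise > 0 and rng.random() < spec.noise:
                expr = expressions[d][int(rng.integers(len(expressions[d])))]
                template = _STRAY_TEMPLATES[int(rng.integers(len(_STRAY_TEMPLATES)))]
                parts.append((template.format(e=expr), []))

        target = float(rng.lognormal(mu, sigma))
        total = sum(len(p) for p, _ in parts) + max(0, len(parts) - 1)
        while True:
            filler = fillers[int(rng.integers(len(fillers)))]
            added = len(filler) + (1 if parts else 0)
            # stop once the target is met; the half-sentence lookahead keeps
            # the mean length centered on the lognormal draw
            if parts and total + added / 2.0 > target:
                break
            parts.append((filler, []))
            total += added

        # assemble text and translate local spans to global offsets
        offset = 0
        chunks: list[str] = []
        spans: list[tuple[int, int, str]] = []
        for sent, local_spans in parts:
            if chunks:
                offset += 1  # joining space
            for s, e, d in local_spans:
                spans.append((offset + s, offset + e, d))
            chunks.append(sent)
            offset += len(sent)
        text = " ".join(chunks)

        planted: dict[str, list[tuple[int, int]]] = {d: [] for d in DIMENSIONS}
        for s, e, d in spans:
            planted[d].append((s, e))
        messages.append(Message(id=mid, text=text, source="synthetic"))
        labels.append(
            AnnotationLabel(
                message_id=mid,
                impact=impact,
                dimensions=dims,
                expressions=[ExpressionSpan(s, e, d) for s, e, d in sorted(spans)],
                annotator="synthetic",
            )
        )
        planted_all[mid] = planted

    corpus = Corpus(messages, provenance=f"synthetic n={spec.n} seed={spec.seed}")
    return SyntheticCorpus(
        corpus=corpus,
        labels=labels,
        planted=planted_all,
        with_health_term=with_term,
        spec=spec,
    )


def planted_to_frame(synth: SyntheticCorpus) -> pd.DataFrame:
    """Planted-span table (message_id, dimension, start, end)."""
    rows = []
    for mid, by_dim in synth.planted.items():
        for d, spans in by_dim.items():
            for s, e in spans:
                rows.append({"message_id": mid, "dimension": d, "start": s, "end": e})
    return pd.DataFrame(rows, columns=["message_id", "dimension", "start", "end"])


def generate_feature_table(
    n: int,
    p_informative: int,
    p_noise: int,
    imbalance: float = 0.5,
    effect_size: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Numeric benchmark data for the modeling operations (no text involved).

    Informative features are class-shifted Gaussians (positive class shifted
    by ``effect_size`` standard deviations); noise features are
    class-independent N(0, 1). ``imbalance`` is the positive-class fraction.
    Returns (X, y, names of the informative features).
    """
    if p_informative < 1:
        raise ValueError("p_informative must be >= 1")
    n_pos = int(round(n * imbalance))
    if min(n_pos, n - n_pos) < 2:
        raise ValueError(f"imbalance {imbalance} yields fewer than 2 minority samples at n={n}")
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    cols = {}
    informative = [f"inf_{i}" for i in range(p_informative)]
    for name in informative:
        cols[name] = rng.normal(0.0, 1.0, size=n) + effect_size * y
    for i in range(p_noise):
        cols[f"noise_{i}"] = rng.normal(0.0, 1.0, size=n)
    X = pd.DataFrame(cols)
    return X, y, informative
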