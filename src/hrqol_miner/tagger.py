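"""Rule-based French morphological tagging.

The feature set needs only coarse morphology: which tokens are pronouns (and
whether they mark a first person singular or plural writer), and which tokens
are verbs in the infinitive, present tense, a simple past tense (imparfait),
or past-participle form. A small deterministic rule tagger over closed word
lists and suffix rules covers this without any statistical model; the tagging
contract is pluggable, so a full statistical tagger can be swapped in by
passing any callable ``tokens -> list[MorphTag]``.

Rules fire in a fixed order (pronoun, finite present, imparfait, infinitive,
past participle, other); a form matching several rules gets the first, which
keeps the tagger total and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

__all__ = ["MorphTag", "RuleTagger", "tag_morphology"]


@dataclass(frozen=True)
class MorphTag:
    token: str
    pos: str  # "verb" | "pronoun" | "other"
    person: str  # "1sg" | "1pl" | "other" | "none"
    tense: str  # "present" | "past" | "none"
    form: str  # "infinitive" | "past_participle" | "finite" | "none"


# --- closed word lists -----------------------------------------------------

PRONOUNS_1SG = frozenset({"je", "j", "me", "moi", "m"})
PRONOUNS_1PL = frozenset({"nous"})
PRONOUNS_OTHER = frozenset(
    {
        "tu", "te", "toi", "t", "il", "elle", "on", "vous", "ils", "elles",
        "se", "s", "lui", "leur", "eux", "celui", "celle", "ceux", "celles",
        "quelqu", "chacun", "personne",
    }
)

# finite present forms, including the auxiliaries être/avoir and frequent
# verbs of forum narratives
PRESENT_FINITE = frozenset(
    {
        "suis", "es", "est", "sommes", "êtes", "sont",
        "ai", "as", "a", "avons", "avez", "ont",
        "vais", "vas", "va", "allons", "allez", "vont",
        "fais", "fait", "faisons", "faites", "font",
        "peux", "peut", "pouvons", "pouvez", "peuvent",
        "veux", "veut", "voulons", "voulez", "veulent",
        "dois", "doit", "devons", "devez", "doivent",
        "sais", "sait", "savons", "savez", "savent",
        "dors", "dort", "dorment", "mange", "manges", "mangent", "mangeons",
        "travaille", "travailles", "travaillent", "travaillons",
        "souffre", "souffres", "souffrent", "souffrons",
        "pleure", "pleures", "pleurent", "pleurons",
        "prends", "prend", "prenons", "prenez", "prennent",
        "sors", "sort", "sortent", "sortons",
        "vois", "voit", "voyons", "voyez", "voient",
        "reste", "restes", "restent", "restons",
        "arrive", "arrives", "arrivent", "arrivons",
        "pèse", "pèsent", "coûte", "coûtent", "paie", "paient", "payons",
        "vis", "vit", "vivent", "vivons",
        "dis", "dit", "disent", "disons",
        "sens", "sent", "sentent", "sentons",
        "pense", "penses", "pensent", "pensons",
        "aide", "aides", "aident", "aidons",
    }
)

# imparfait (simple past of narration); closed list of frequent forms
IMPARFAIT_FINITE = frozenset(
    {
        "étais", "était", "étions", "étiez", "étaient",
        "avais", "avait", "avions", "aviez", "avaient",
        "allais", "allait", "allaient",
        "faisais", "faisait", "faisaient",
        "pouvais", "pouvait", "pouvaient",
        "devais", "devait", "devaient",
        "dormais", "dormait", "dormaient",
        "travaillais", "travaillait", "travaillaient",
        "souffrais", "souffrait", "souffraient",
        "sortais", "sortait", "sortaient",
        "vivais", "vivait", "vivaient",
        "voulais", "voulait", "voulaient",
        "payais", "payait", "payaient",
    }
)

INFINITIVES = frozenset(
    {
        "être", "avoir", "aller", "faire", "dormir", "manger", "travailler",
        "souffrir", "pleurer", "sortir", "payer", "marcher", "courir",
        "vivre", "voir", "prendre", "partir", "rester", "parler", "penser",
        "aider", "changer", "arrêter", "continuer", "bouger", "respirer",
        "dire", "savoir", "pouvoir", "vouloir", "devoir", "sentir",
        "raconter", "tenir", "supporter", "gérer", "expliquer",
    }
)

IRREGULAR_PARTICIPLES = frozenset(
    {"pris", "mis", "vu", "eu", "été", "venu", "parti", "dormi", "souffert", "vécu", "pu", "dû", "su", "voulu"}
)

_PARTICIPLE_SUFFIXES = ("é", "ée", "és", "ées")


class RuleTagger:
    """Deterministic closed-list French tagger (the bundled default)."""

    def __call__(self, tokens: Sequence[str]) -> list[MorphTag]:
        return [self.tag_token(t) for t in tokens]

    @staticmethod
    def tag_token(token: str) -> MorphTag:
        t = token.lower()
        if t in PRONOUNS_1SG:
            return MorphTag(token, "pronoun", "1sg", "none", "none")
        if t in PRONOUNS_1PL:
            return MorphTag(token, "pronoun", "1pl", "none", "none")
        if t in PRONOUNS_OTHER:
            return MorphTag(token, "pronoun", "other", "none", "none")
        if t in PRESENT_FINITE:
            return MorphTag(token, "verb", "other", "present", "finite")
        if t in IMPARFAIT_FINITE:
            return MorphTag(token, "verb", "other", "past", "finite")
        if t in INFINITIVES:
            return MorphTag(token, "verb", "none", "none", "infinitive")
        if t in IRREGULAR_PARTICIPLES or (
            len(t) > 2 and any(t.endswith(suf) for suf in _PARTICIPLE_SUFFIXES)
        ):
            return MorphTag(token, "verb", "none", "past", "past_participle")
        return MorphTag(token, "other", "none", "none", "none")


Tagger = Callable[[Sequence[str]], list[MorphTag]]

_DEFAULT = RuleTagger()


def tag_morphology(tokens: Sequence[str], tagger: Tagger | None = None) -> list[MorphTag]:
    """Tag tokens with the given tagger (default: the bundled rule tagger)."""
    return (tagger or _DEFAULT)(list(tokens))
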