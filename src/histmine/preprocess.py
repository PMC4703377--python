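"""Tokenization, rule-based lemmatization/POS tagging, and vocabularies.

The distributional models downstream operate on *lexical units*: lowercased
lemmas that survive stop-word filtering. Lemmatization and POS tagging sit
behind a pluggable interface so that any external tagger can be substituted;
the bundled default is a deterministic rule system (no external models),
which keeps every pipeline output reproducible bit-for-bit.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from ._stopwords import DEFAULT_STOPWORDS, load_stopwords  # noqa: F401 (re-export)

COARSE_TAGS = ("NOUN", "VERB", "ADJ", "DET", "PREP", "OTHER")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    sent_index: int
    lemma: str | None = None
    pos: str | None = None

    @property
    def is_word(self) -> bool:
        return any(ch.isalnum() for ch in self.surface)


@dataclass
class Vocabulary:
    """Frequency-ranked lexical units, stop-words removed, truncated at ``cap``."""

    units: list[tuple[str, int]]
    cap: int
    stopset: frozenset[str]

    def __post_init__(self) -> None:
        self._index = {lemma: i for i, (lemma, _) in enumerate(self.units)}

    def __contains__(self, lemma: str) -> bool:
        return lemma in self._index

    def __len__(self) -> int:
        return len(self.units)

    @property
    def frequencies(self) -> dict[str, int]:
        return dict(self.units)


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

# words keep internal hyphens/apostrophes ("cerebro-spinal"); everything else
# splits into single punctuation tokens
_TOKEN = re.compile(r"\w+(?:[-']\w+)*|[^\w\s]", re.UNICODE)

#: abbreviations whose trailing period does not end a sentence
ABBREVIATIONS = frozenset({
    "dr", "mr", "mrs", "ms", "prof", "st", "no", "vol", "fig", "e.g", "i.e",
    "etc", "vs", "cf", "jan", "feb", "mar", "apr", "jun", "jul", "aug", "sep",
    "oct", "nov", "dec",
})

_SENT_END = frozenset(".!?")


def tokenize(text: str) -> list[Token]:
    """Split text into offset-carrying tokens with sentence indices.

    Sentence boundaries fall after ``.``, ``!`` or ``?`` followed by
    whitespace and an uppercase letter, guarded by an abbreviation list.
    Deterministic; empty text yields an empty list.
    """
    tokens: list[Token] = []
    sent = 0
    prev_word: str | None = None
    pending_break = False
    for m in _TOKEN.finditer(text):
        surface = m.group()
        if pending_break:
            sent += 1
            pending_break = False
        tokens.append(Token(surface, m.start(), m.end(), sent))
        if surface in _SENT_END:
            guarded = (surface == "." and prev_word is not None
                       and prev_word.lower().rstrip(".") in ABBREVIATIONS)
            if not guarded:
                # break only if followed by whitespace + uppercase
                rest = text[m.end():]
                stripped = rest.lstrip()
                if stripped and len(stripped) < len(rest) and stripped[0].isupper():
                    pending_break = True
        if any(ch.isalnum() for ch in surface):
            prev_word = surface
    return tokens


# ---------------------------------------------------------------------------
# lemmatization / POS
# ---------------------------------------------------------------------------

class LemmatizerBackend(Protocol):
    """Interface for pluggable linguistic processing backends."""

    def analyze(self, surface: str) -> tuple[str, str]:
        """Return ``(lemma, coarse_pos)`` for one token surface."""


_DETERMINERS = frozenset({"the", "a", "an", "this", "that", "these", "those",
                          "every", "each", "either", "neither", "some", "any",
                          "no"})
_PREPOSITIONS = frozenset({"of", "to", "in", "on", "at", "by", "for", "with",
                           "from", "into", "onto", "upon", "under", "over",
                           "between", "among", "amongst", "through", "during",
                           "without", "within", "against", "about", "towards",
                           "toward", "via", "per"})
_VERB_LEXICON = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "be": "be", "am": "be", "has": "have", "have": "have", "had": "have",
    "does": "do", "do": "do", "did": "do", "caused": "cause",
    "causes": "cause", "cause": "cause",
}
# words whose surface ends like an inflection but must not be stripped
_STRIP_EXCEPTIONS = frozenset({
    "during", "thing", "things", "nothing", "something", "anything", "being",
    "evening", "morning", "lung", "lungs", "king", "spring", "red", "bed",
    "need", "feed", "seed", "deed", "indeed", "hundred", "naked", "sacred",
    "species", "series", "analysis", "diagnosis", "tuberculosis", "phthisis",
    "this", "his", "its", "was", "is", "us", "thus", "gas", "atlas", "news",
    "always", "perhaps", "miasmas",
})

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "al", "ic", "ary")


def _singularize(word: str) -> str:
    if word in _STRIP_EXCEPTIONS or len(word) <= 3 or not word.endswith("s"):
        return word
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("sses", "xes", "zes", "ches", "shes")):
        return word[:-2]
    if word.endswith(("ss", "us", "is")):
        return word
    return word[:-1]


class RuleLemmatizer:
    """Dependency-free deterministic lemmatizer and heuristic POS tagger.

    Closed-class words come from small lexica; nouns are singularized by
    suffix rules; -ing/-ed verb forms are stripped with an exception list.
    Intentionally simple: adequate for frequency ranking and context
    windows, not a linguistics benchmark.
    """

    def analyze(self, surface: str) -> tuple[str, str]:
        low = surface.lower()
        if not any(ch.isalnum() for ch in low):
            return low, "OTHER"
        if low in _DETERMINERS:
            return low, "DET"
        if low in _PREPOSITIONS:
            return low, "PREP"
        if low in _VERB_LEXICON:
            return _VERB_LEXICON[low], "VERB"
        if low not in _STRIP_EXCEPTIONS:
            if low.endswith("ing") and len(low) > 5:
                stem = low[:-3]
                if len(stem) > 2 and stem[-1] == stem[-2]:  # running -> run
                    stem = stem[:-1]
                return stem + ("e" if stem.endswith(("caus", "produc")) else ""), "VERB"
            if low.endswith("ed") and len(low) > 4:
                stem = low[:-2]
                return stem + ("e" if stem.endswith(("caus", "produc")) else ""), "VERB"
        if low.endswith(_ADJ_SUFFIXES) and len(low) > 4:
            return low, "ADJ"
        return _singularize(low), "NOUN"


def lemmatize_pos(tokens: Sequence[Token],
                  backend: LemmatizerBackend | None = None) -> list[Token]:
    """Enrich tokens with lemma and coarse POS via the chosen backend.

    A backend failure on a token downgrades it to ``lemma=lowercased
    surface, pos=OTHER`` rather than aborting the document.
    """
    backend = backend or RuleLemmatizer()
    out: list[Token] = []
    for tok in tokens:
        try:
            lemma, pos = backend.analyze(tok.surface)
        except Exception:  # noqa: BLE001 - backend contract: degrade, not fail
            lemma, pos = tok.surface.lower(), "OTHER"
        out.append(replace(tok, lemma=lemma, pos=pos))
    return out


def preprocess_text(text: str,
                    backend: LemmatizerBackend | None = None) -> list[Token]:
    """tokenize + lemmatize in one call."""
    return lemmatize_pos(tokenize(text), backend)


def sentences(tokens: Sequence[Token]) -> list[list[Token]]:
    """Group a token stream by sentence index (ascending)."""
    out: list[list[Token]] = []
    for tok in tokens:
        while tok.sent_index >= len(out):
            out.append([])
        out[tok.sent_index].append(tok)
    return [s for s in out if s]


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

def build_vocabulary(token_streams: Iterable[Sequence[Token]],
                     cap: int = 150_000,
                     stopwords: frozenset[str] = DEFAULT_STOPWORDS,
                     ) -> Vocabulary:
    """Frequency-ranked lexical units over preprocessed documents.

    Stop-words and punctuation are excluded; ties in frequency break
    lexicographically; the list is truncated at ``cap``.
    """
    if cap < 1:
        raise ValueError("vocabulary cap must be >= 1")
    counts: Counter[str] = Counter()
    for stream in token_streams:
        for tok in stream:
            if tok.lemma is None:
                raise ValueError("tokens must be lemmatized before vocabulary build")
            if tok.is_word and tok.lemma not in stopwords:
                counts[tok.lemma] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:cap]
    return Vocabulary(ranked, cap, frozenset(stopwords))


def export_conll(tokens: Sequence[Token], path: str | Path) -> None:
    """CoNLL-style TSV export: token, lemma, pos, sentence, start, end."""
    lines = ["token\tlemma\tpos\tsent\tstart\tend"]
    for t in tokens:
        lines.append(f"{t.surface}\t{t.lemma or ''}\t{t.pos or ''}\t"
                     f"{t.sent_index}\t{t.start}\t{t.end}")
    Path(path).write_text("".join(l + "\n" for l in lines), "utf-8")
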