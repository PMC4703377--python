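"""Dictionary-based entity pre-annotation and sequence-tagger feature export.

A labeled lexicon (terms carrying external category labels, e.g. semantic
types from a large medical metathesaurus) is mapped onto the historical
annotation scheme's entity categories through per-category rules. Each rule
may impose filters — minimum token length, noun head, noun-phrase shape —
that trade recall for precision during pre-annotation. The same machinery
produces token-level B/I/O feature tables for training external sequence
taggers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import EntitySpan, Thesaurus
from .preprocess import LemmatizerBackend, Token, preprocess_text
from .dsm import _Matcher, term_key

#: POS tags allowed inside a maximal noun-phrase run (chunker approximation)
_NP_TAGS = frozenset({"DET", "ADJ", "NOUN"})


@dataclass(frozen=True)
class MappingRule:
    """Maps a set of external categories onto one target entity category."""

    external_categories: frozenset[str]
    target: str
    require_noun_phrase: bool = False
    min_tokens: int = 1
    require_noun_head: bool = False

    def __post_init__(self) -> None:
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")


@dataclass
class Lexicon:
    """Longest-match index: lemma-sequence -> external categories."""

    entries: dict[str, set[str]] = field(default_factory=dict)
    n_skipped: int = 0  # terms under unmapped external categories

    def __len__(self) -> int:
        return len(self.entries)

    def matcher(self) -> _Matcher:
        return _Matcher(self.entries)


def compile_lexicon(thesaurus: Thesaurus,
                    rules: Sequence[MappingRule],
                    backend: LemmatizerBackend | None = None) -> Lexicon:
    """Index a labeled thesaurus for longest-match scanning.

    Terms are keyed on their lemma sequences (same normalization as
    document text); terms whose external categories are not covered by any
    rule are skipped and counted.
    """
    mapped = set()
    for rule in rules:
        mapped |= rule.external_categories
    entries: dict[str, set[str]] = {}
    skipped = 0
    for term in sorted(thesaurus.terms):
        cats = thesaurus.term_categories.get(term, set())
        usable = cats & mapped
        if not usable:
            skipped += 1
            continue
        key = term_key(term, backend)
        if key:
            entries.setdefault(key, set()).update(usable)
    return Lexicon(entries, skipped)


def _np_runs(tokens: Sequence[Token]) -> list[tuple[int, int]]:
    """Maximal DET/ADJ/NOUN token runs (the bundled chunker approximation)."""
    runs: list[tuple[int, int]] = []
    start: int | None = None
    for i, tok in enumerate(tokens):
        if tok.pos in _NP_TAGS and tok.is_word:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(tokens)))
    return runs


def _passes(rule: MappingRule, tokens: Sequence[Token],
            start: int, end: int, runs: Sequence[tuple[int, int]]) -> bool:
    if end - start < rule.min_tokens:
        return False
    if rule.require_noun_head and tokens[end - 1].pos != "NOUN":
        return False
    if rule.require_noun_phrase:
        if not any(rs <= start and end <= re_ for rs, re_ in runs):
            return False
    return True


def tag_document(tokens: Sequence[Token], lexicon: Lexicon,
                 rules: Sequence[MappingRule],
                 doc_id: str = "") -> list[EntitySpan]:
    """Longest-match dictionary pre-annotation with per-rule filtering.

    Candidates come from a non-overlapping left-to-right scan over lemma
    sequences; each surviving candidate is emitted with the mapped target
    category at the original character offsets. If several rules map one
    candidate to different targets, the lexicographically first target
    wins (spans must not overlap).
    """
    word_tokens = [t for t in tokens if t.is_word]
    lemmas = [t.lemma or t.surface.lower() for t in word_tokens]
    runs = _np_runs(word_tokens)
    spans: list[EntitySpan] = []
    counter = 0
    for start, end, key in lexicon.matcher().scan(lemmas):
        ext_cats = lexicon.entries[key]
        targets = sorted({
            rule.target for rule in rules
            if rule.external_categories & ext_cats
            and _passes(rule, word_tokens, start, end, runs)
        })
        if not targets:
            continue
        counter += 1
        c_start = word_tokens[start].start
        c_end = word_tokens[end - 1].end
        spans.append(EntitySpan(f"D{counter}", doc_id, c_start, c_end,
                                targets[0], surface=""))
    return spans


def tag_text(text: str, lexicon: Lexicon, rules: Sequence[MappingRule],
             doc_id: str = "",
             backend: LemmatizerBackend | None = None) -> list[EntitySpan]:
    """Convenience wrapper: preprocess then tag, filling in surfaces."""
    tokens = preprocess_text(text, backend)
    return [
        EntitySpan(s.span_id, s.doc_id, s.start, s.end, s.category,
                   text[s.start:s.end])
        for s in tag_document(tokens, lexicon, rules, doc_id)
    ]


# ---------------------------------------------------------------------------
# feature export
# ---------------------------------------------------------------------------

def _bio_column(word_tokens: Sequence[Token],
                spans: Iterable[EntitySpan]) -> list[str]:
    labels = ["O"] * len(word_tokens)
    for span in spans:
        covered = [i for i, t in enumerate(word_tokens)
                   if t.start < span.end and t.end > span.start]
        for j, i in enumerate(covered):
            labels[i] = ("B-" if j == 0 else "I-") + span.category
    return labels


def export_features(tokens: Sequence[Token],
                    lexicon_hits: Sequence[EntitySpan],
                    gold: Sequence[EntitySpan] | None = None,
                    ) -> pd.DataFrame:
    """Token-level feature table for external sequence taggers.

    One row per word token: surface, lemma, pos, noun-phrase-chunk B/I/O,
    one B/I/O column per dictionary-hit category, and (when gold spans are
    given) a gold B/I/O label column. Gold spans not aligned to token
    boundaries are clipped to the covering tokens.
    """
    word_tokens = [t for t in tokens if t.is_word]
    rows = {
        "surface": [t.surface for t in word_tokens],
        "lemma": [t.lemma or "" for t in word_tokens],
        "pos": [t.pos or "" for t in word_tokens],
    }
    chunk = ["O"] * len(word_tokens)
    for rs, re_ in _np_runs(word_tokens):
        for i in range(rs, re_):
            chunk[i] = "B-NP" if i == rs else "I-NP"
    rows["chunk"] = chunk
    categories = sorted({s.category for s in lexicon_hits})
    for cat in categories:
        col = _bio_column(word_tokens,
                          [s for s in lexicon_hits if s.category == cat])
        rows[f"dict_{cat}"] = col
    if gold is not None:
        rows["gold"] = _bio_column(word_tokens, gold)
    return pd.DataFrame(rows)


def write_features_tsv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# rule configuration I/O
# ---------------------------------------------------------------------------

def read_mapping_rules(path: str | Path) -> list[MappingRule]:
    """Parse a mapping-rule config.

    One rule per line::

        external_cat1|external_cat2<TAB>Target<TAB>flag,flag,min_tokens=2

    Flags: ``noun_phrase``, ``noun_head``, ``min_tokens=N``.
    """
    rules = []
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed rule line: {line!r}")
        externals = frozenset(p.strip() for p in parts[0].split("|") if p.strip())
        target = parts[1].strip()
        np_flag = head_flag = False
        min_tokens = 1
        if len(parts) > 2 and parts[2].strip():
            for flag in parts[2].split(","):
                flag = flag.strip()
                if flag == "noun_phrase":
                    np_flag = True
                elif flag == "noun_head":
                    head_flag = True
                elif flag.startswith("min_tokens="):
                    min_tokens = int(flag.split("=", 1)[1])
                else:
                    raise ValueError(f"unknown rule flag {flag!r}")
        rules.append(MappingRule(externals, target, np_flag, min_tokens, head_flag))
    return rules


def write_mapping_rules(rules: Sequence[MappingRule], path: str | Path) -> None:
    lines = []
    for r in rules:
        flags = []
        if r.require_noun_phrase:
            flags.append("noun_phrase")
        if r.require_noun_head:
            flags.append("noun_head")
        if r.min_tokens > 1:
            flags.append(f"min_tokens={r.min_tokens}")
        lines.append("|".join(sorted(r.external_categories)) + "\t" + r.target
                     + "\t" + ",".join(flags))
    Path(path).write_text("".join(l + "\n" for l in lines), "utf-8")
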