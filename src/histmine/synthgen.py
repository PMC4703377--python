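"""Seeded generator of synthetic historical-style corpora.

The generator emulates the statistical structure distributional models
rely on: terms that appear in similar textual contexts carry similar
meaning. Each planted concept owns a disjoint set of dedicated signature
context words; every synonym of a concept is emitted surrounded by draws
from that signature, diluted by a configurable background-noise rate.
Era maps assign synonyms to year ranges, emulating diachronic variants
(phthisis -> tuberculosis); gold entity spans and a gold thesaurus make
the corpus a complete test substrate for the rest of the toolkit.

Deterministic by contract: the same config (seed included) yields
byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import corpus_io
from .corpus_io import Document, EntitySpan, Thesaurus


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; the defaults define the bundled default scenario.

    20 concepts x 2 synonyms with 8 dedicated signature words each, a
    400-word background vocabulary, 10% window noise, and 8,000 sentences
    (80 documents x 100) — i.e. about 200 mentions per planted term —
    over the 1850-1969 year range.
    """

    seed: int
    n_concepts: int = 20
    synonyms_per_concept: int = 2
    multiword_fraction: float = 0.0
    categories: tuple[str, ...] = ("Condition",)
    signature_size: int = 8
    background_vocab_size: int = 400
    noise_rate: float = 0.1
    n_docs: int = 80
    sentences_per_doc: int = 100
    mentions_per_sentence: int = 1
    window_words: int = 3
    era_map: tuple[tuple[int, int], ...] | None = None
    year_range: tuple[int, int] = (1850, 1969)

    def __post_init__(self) -> None:
        for name in ("n_concepts", "synonyms_per_concept", "signature_size",
                     "background_vocab_size", "n_docs", "sentences_per_doc",
                     "mentions_per_sentence", "window_words"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("multiword_fraction", "noise_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (lo, hi) with lo <= hi")
        if self.era_map is not None:
            if len(self.era_map) != self.synonyms_per_concept:
                raise ValueError("era_map needs one year range per synonym")
            lo, hi = self.year_range
            for a, b in self.era_map:
                if a > b or b < lo or a > hi:
                    raise ValueError("era_map inconsistent with year_range")
            for y in range(lo, hi + 1):
                if not any(a <= y <= b for a, b in self.era_map):
                    raise ValueError(f"era_map leaves year {y} uncovered")


@dataclass
class SynthCorpus:
    """A generated corpus plus its gold annotations and manifest."""

    documents: list[Document]
    entities: dict[str, list[EntitySpan]]       # doc_id -> gold spans
    thesaurus: Thesaurus                        # concept -> planted synonyms
    categories: dict[str, str]                  # concept_id -> entity category
    eras: dict[str, tuple[int, int]] | None     # term -> active year range
    manifest: dict = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return sorted(self.thesaurus.terms)

    def write(self, out_dir: str | Path) -> Path:
        """Emit exactly the formats corpus_io consumes: .txt + metadata TSV
        + .ann per document + thesaurus TSV + manifest JSON."""
        out_dir = Path(out_dir)
        text_dir = out_dir / "texts"
        corpus_io.write_documents(self.documents, text_dir,
                                  out_dir / "metadata.tsv")
        for doc in self.documents:
            corpus_io.write_brat(self.entities[doc.doc_id], [],
                                 text_dir / f"{doc.doc_id}.ann")
        corpus_io.write_thesaurus(self.thesaurus, out_dir / "thesaurus.tsv")
        (out_dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n", "utf-8")
        return out_dir


def _term_surfaces(config: SynthConfig, rng: np.random.Generator,
                   ) -> list[list[str]]:
    """Synonym surfaces per concept; a fraction are two-word terms.

    Multi-word surfaces pair a synonym-specific modifier with a shared
    per-concept head word, mirroring patterns like "scarlet fever" /
    "scarlatinal fever".
    """
    surfaces: list[list[str]] = []
    for c in range(config.n_concepts):
        multi = rng.random() < config.multiword_fraction
        row = []
        for s in range(config.synonyms_per_concept):
            if multi:
                row.append(f"c{c}mod{s} c{c}head")
            else:
                row.append(f"c{c}syn{s}")
        surfaces.append(row)
    return surfaces


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate a corpus of planted synonym sets with gold annotations.

    Per sentence: a concept is sampled, a surface synonym chosen
    (era-conditioned on the document year when an era map is set), and the
    term emitted surrounded by ``window_words`` draws per side from a
    (1 - noise_rate) signature / noise_rate background mixture, padded
    with background words. Gold spans are recorded at exact character
    offsets. All sampling flows from one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    signatures = [
        [f"c{c}sig{i}" for i in range(config.signature_size)]
        for c in range(config.n_concepts)
    ]
    background = [f"bgw{i}" for i in range(config.background_vocab_size)]
    surfaces = _term_surfaces(config, rng)

    entries = {f"C{c}": set(surfaces[c]) for c in range(config.n_concepts)}
    categories = {f"C{c}": config.categories[c % len(config.categories)]
                  for c in range(config.n_concepts)}
    eras = None
    if config.era_map is not None:
        eras = {}
        for c in range(config.n_concepts):
            for s, surface in enumerate(surfaces[c]):
                eras[surface] = config.era_map[s]

    def draw_context(sig: Sequence[str]) -> str:
        if rng.random() < config.noise_rate:
            return background[rng.integers(len(background))]
        return sig[rng.integers(len(sig))]

    def draw_background() -> str:
        return background[rng.integers(len(background))]

    documents: list[Document] = []
    entities: dict[str, list[EntitySpan]] = {}
    lo, hi = config.year_range
    w = config.window_words
    for d in range(config.n_docs):
        doc_id = f"doc{d:04d}"
        year = int(rng.integers(lo, hi + 1))
        parts: list[str] = []
        spans: list[EntitySpan] = []
        pos = 0
        span_counter = 0
        for _ in range(config.sentences_per_doc):
            words: list[str] = []
            mention_slots: list[tuple[int, str, str]] = []  # (index, term, cid)
            for m in range(config.mentions_per_sentence):
                c = int(rng.integers(config.n_concepts))
                if config.era_map is not None:
                    active = [s for s, (a, b) in enumerate(config.era_map)
                              if a <= year <= b]
                    s = active[0]  # hard era boundaries: deterministic in year
                else:
                    s = int(rng.integers(config.synonyms_per_concept))
                term = surfaces[c][s]
                words.append(draw_background())
                words.extend(draw_context(signatures[c]) for _ in range(w))
                mention_slots.append((len(words), term, f"C{c}"))
                words.append(term)
                words.extend(draw_context(signatures[c]) for _ in range(w))
            words.append(draw_background())
            # capitalize the sentence opener so the tokenizer sees a boundary
            words[0] = words[0].capitalize()
            sentence = " ".join(words) + "."
            # character offsets of each mention within the document
            cursor = pos
            for i, word in enumerate(words):
                matches = [t for idx, t, cid in mention_slots if idx == i]
                if matches:
                    term = matches[0]
                    cid = next(cid for idx, t, cid in mention_slots if idx == i)
                    span_counter += 1
                    spans.append(EntitySpan(
                        f"T{span_counter}", doc_id, cursor,
                        cursor + len(term), categories[cid], term))
                cursor += len(word) + 1
            parts.append(sentence)
            pos += len(sentence) + 1
        text = " ".join(parts)
        # re-derive surfaces from the final text as a self-check
        spans = [
            EntitySpan(s.span_id, s.doc_id, s.start, s.end, s.category,
                       text[s.start:s.end])
            for s in spans
        ]
        for s in spans:
            if s.surface != text[s.start:s.end] or " " + s.surface + " " not in f" {text} ":
                raise AssertionError("gold span bookkeeping error")
        documents.append(Document(doc_id, "SYNTH", year, text))
        entities[doc_id] = spans

    thesaurus = Thesaurus({cid: set(terms) for cid, terms in entries.items()})
    manifest = {"config": asdict(config), "generator": "histmine.synthgen"}
    return SynthCorpus(documents, entities, thesaurus, categories, eras, manifest)
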