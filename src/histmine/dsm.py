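"""Count-based distributional semantic models with LLR weighting.

The engine characterizes each term by a sparse context vector: the lexical
units occurring within a fixed window around its corpus occurrences, each
weighted by the log-likelihood-ratio statistic (Dunning's G²) of the 2x2
term/unit co-occurrence table. Related terms are then the nearest neighbors
under cosine similarity.

Multi-word terms are handled three ways:

* **SA** (standard approach): the phrase is matched as a single unit and its
  own occurrences provide the contexts.
* **BAM** (basic additive model): the constituent words' vectors are summed
  over the union of their supports.
* **BMM** (basic multiplicative model): element-wise product over the
  intersection of supports — only context shared by *all* constituents
  survives.

Negative associations (observed co-occurrence at or below expectation) are
clamped to zero, keeping vectors non-negative and cosine on the [0, 1]
scale that the 0.8 pair-export threshold presumes.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import Document, Thesaurus
from .preprocess import (DEFAULT_STOPWORDS, LemmatizerBackend, Token,
                         Vocabulary, build_vocabulary, preprocess_text,
                         sentences)

MODELS = ("SA", "BAM", "BMM")


@dataclass(frozen=True)
class DsmConfig:
    """Every numeric knob of the distributional pipeline.

    Defaults follow the study conditions this engine was designed around:
    a +-3-token context window, a 150,000-unit vocabulary cap, top-20
    neighbor lists, source terms occurring strictly between 20 and 1000
    times (at most 500 of them), a 0.8 cosine threshold for pair export,
    and a minimum corpus frequency of 5 for inventory candidates.
    """

    window: int = 3
    cap: int = 150_000
    k: int = 20
    source_min_count: int = 20
    source_max_count: int = 1000
    n_sources: int = 500
    pair_threshold: float = 0.8
    inventory_min_freq: int = 5
    model: str = "SA"
    cross_sentence: bool = False
    per_collection: bool = True

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 < self.pair_threshold <= 1):
            raise ValueError("pair_threshold must be in (0, 1]")
        if self.source_min_count >= self.source_max_count:
            raise ValueError("source_min_count must be < source_max_count")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")


@dataclass
class CooccurrenceCounts:
    """Raw (term, lexical unit) co-occurrence counts over window slots."""

    counts: dict[str, Counter]

    def term_totals(self) -> dict[str, int]:
        return {t: sum(c.values()) for t, c in self.counts.items()}

    def unit_totals(self) -> Counter:
        total: Counter = Counter()
        for c in self.counts.values():
            total.update(c)
        return total

    @property
    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())


@dataclass(frozen=True)
class ContextVector:
    """Sparse lexical-unit -> non-negative weight map for one term."""

    term: str
    model: str
    weights: Mapping[str, float]

    @property
    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))

    def is_zero(self) -> bool:
        return all(w == 0.0 for w in self.weights.values())


@dataclass(frozen=True)
class NeighborList:
    """Ranked related terms for one source (descending cosine, <= k items)."""

    source: str
    neighbors: tuple[tuple[str, float], ...]

    def targets(self, k: int | None = None) -> list[str]:
        items = self.neighbors if k is None else self.neighbors[:k]
        return [t for t, _ in items]


@dataclass
class TermInventory:
    """source term -> NeighborList, plus build provenance."""

    lists: dict[str, NeighborList]
    provenance: dict

    def __len__(self) -> int:
        return len(self.lists)

    def __iter__(self):
        return iter(self.lists.items())


# ---------------------------------------------------------------------------
# term matching
# ---------------------------------------------------------------------------

def term_key(term: str, backend: LemmatizerBackend | None = None) -> str:
    """Canonical lemma-sequence key for a (possibly multi-word) term."""
    toks = [t for t in preprocess_text(term, backend) if t.is_word]
    return " ".join(t.lemma or "" for t in toks)


class _Matcher:
    """Longest-match, non-overlapping, left-to-right lemma-sequence scanner."""

    def __init__(self, terms: Iterable[str]):
        self._by_first: dict[str, list[tuple[str, ...]]] = {}
        for term in terms:
            seq = tuple(term.split())
            if not seq:
                continue
            self._by_first.setdefault(seq[0], []).append(seq)
        for seqs in self._by_first.values():
            seqs.sort(key=len, reverse=True)

    def scan(self, lemmas: Sequence[str]) -> list[tuple[int, int, str]]:
        """Yield (start, end, term_key) over a lemma sequence."""
        out: list[tuple[int, int, str]] = []
        i = 0
        n = len(lemmas)
        while i < n:
            matched = False
            for seq in self._by_first.get(lemmas[i], ()):
                j = i + len(seq)
                if j <= n and tuple(lemmas[i:j]) == seq:
                    out.append((i, j, " ".join(seq)))
                    i = j
                    matched = True
                    break
            if not matched:
                i += 1
        return out


def _context_units(stream: Sequence[Token], cross_sentence: bool,
                   ) -> list[list[str | None]]:
    """Per-window-segment lemma lists; punctuation kept as positions."""
    segments = [list(stream)] if cross_sentence else sentences(stream)
    return [[t.lemma for t in seg] for seg in segments]


def term_frequencies(token_streams: Iterable[Sequence[Token]],
                     terms: Iterable[str],
                     cross_sentence: bool = False) -> Counter:
    """Corpus occurrence counts per term under longest-match scanning."""
    matcher = _Matcher(terms)
    freqs: Counter = Counter()
    for stream in token_streams:
        for seg in _context_units(stream, cross_sentence):
            for _, _, key in matcher.scan(seg):
                freqs[key] += 1
    return freqs


def count_contexts(token_streams: Iterable[Sequence[Token]],
                   terms: Iterable[str],
                   config: DsmConfig,
                   vocabulary: Vocabulary) -> CooccurrenceCounts:
    """Collect windowed co-occurrence counts for each term occurrence.

    For every occurrence (longest-match, non-overlapping, left-to-right),
    up to ``config.window`` raw token positions on each side of the phrase
    boundaries are collected, truncated at sentence boundaries unless
    ``cross_sentence``. Stop-words and out-of-vocabulary lemmas occupy
    positions but are dropped from the collected slots; interior words of
    a multi-word occurrence are never context.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("count_contexts requires a non-empty term list")
    matcher = _Matcher(terms)
    counts: dict[str, Counter] = {t: Counter() for t in (" ".join(t.split()) for t in terms)}
    w = config.window
    for stream in token_streams:
        for seg in _context_units(stream, config.cross_sentence):
            for start, end, key in matcher.scan(seg):
                slots = seg[max(0, start - w):start] + seg[end:end + w]
                for lemma in slots:
                    if lemma is not None and lemma in vocabulary:
                        counts[key][lemma] += 1
    return CooccurrenceCounts(counts)


# ---------------------------------------------------------------------------
# log-likelihood-ratio weighting
# ---------------------------------------------------------------------------

def g2_statistic(k11, k12, k21, k22):
    """Dunning's G² for 2x2 contingency tables (vectorized).

    G² = 2 * sum_ij k_ij * ln(k_ij / E_ij), with E_ij = row_i * col_j / N
    and the convention 0 * ln 0 = 0. Accepts scalars or arrays.
    """
    k = np.stack([np.asarray(x, dtype=np.float64) for x in (k11, k12, k21, k22)])
    if np.any(k < 0):
        raise ValueError("contingency cells must be non-negative")
    n = k.sum(axis=0)
    rows = np.stack([k[0] + k[1], k[0] + k[1], k[2] + k[3], k[2] + k[3]])
    cols = np.stack([k[0] + k[2], k[1] + k[3], k[0] + k[2], k[1] + k[3]])
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows * cols / n
        terms = np.where(k > 0, k * np.log(k / expected), 0.0)
    g2 = 2.0 * np.nansum(terms, axis=0)
    # tables with N == 0 carry no evidence
    g2 = np.where(n > 0, g2, 0.0)
    # guard tiny negative round-off
    return np.maximum(g2, 0.0) if g2.ndim else float(max(g2, 0.0))


def llr_weight(counts: CooccurrenceCounts, model: str = "SA",
               ) -> dict[str, ContextVector]:
    """Turn raw co-occurrence counts into LLR-weighted context vectors.

    Each (term t, unit u) pair is scored by G² over the table
    ``k11 = c(t,u), k12 = c(.,u) - k11, k21 = c(t,.) - k11,
    k22 = N - k11 - k12 - k21``; negative associations (k11 <= E11) are
    clamped to zero.
    """
    unit_totals = counts.unit_totals()
    term_totals = counts.term_totals()
    n = counts.total
    vectors: dict[str, ContextVector] = {}
    for term, row in counts.counts.items():
        if not row:
            vectors[term] = ContextVector(term, model, {})
            continue
        units = sorted(row)
        k11 = np.array([row[u] for u in units], dtype=np.float64)
        col = np.array([unit_totals[u] for u in units], dtype=np.float64)
        rtot = float(term_totals[term])
        k12 = col - k11
        k21 = rtot - k11
        k22 = n - k11 - k12 - k21
        if np.any(k12 < 0) or np.any(k21 < 0) or np.any(k22 < 0):
            raise ValueError(f"inconsistent marginals for term {term!r}")
        weights = g2_statistic(k11, k12, k21, k22)
        expected = rtot * col / n
        weights = np.where(k11 > expected, weights, 0.0)
        vectors[term] = ContextVector(
            term, model,
            {u: float(wt) for u, wt in zip(units, weights) if wt > 0.0})
    return vectors


# ---------------------------------------------------------------------------
# composition and similarity
# ---------------------------------------------------------------------------

def compose_bam(constituents: Sequence[ContextVector]) -> ContextVector:
    """Additive composition: union of supports, weights summed."""
    if not constituents:
        raise ValueError("compose_bam requires at least one constituent")
    weights: dict[str, float] = {}
    for vec in constituents:
        for unit, w in vec.weights.items():
            weights[unit] = weights.get(unit, 0.0) + w
    term = " ".join(v.term for v in constituents)
    return ContextVector(term, "BAM", weights)


def compose_bmm(constituents: Sequence[ContextVector]) -> ContextVector:
    """Multiplicative composition: intersection of supports, weights multiplied."""
    if not constituents:
        raise ValueError("compose_bmm requires at least one constituent")
    support = set(constituents[0].weights)
    for vec in constituents[1:]:
        support &= set(vec.weights)
    weights = {}
    for unit in support:
        w = 1.0
        for vec in constituents:
            w *= vec.weights[unit]
        weights[unit] = w
    term = " ".join(v.term for v in constituents)
    return ContextVector(term, "BMM", weights)


def cosine(v1: ContextVector, v2: ContextVector) -> float:
    """Cosine similarity of two non-negative sparse vectors; 0 if either is zero."""
    if len(v1.weights) > len(v2.weights):
        v1, v2 = v2, v1
    dot = sum(w * v2.weights.get(u, 0.0) for u, w in v1.weights.items())
    n1, n2 = v1.norm, v2.norm
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return min(1.0, dot / (n1 * n2))


def top_k_neighbors(source: str, candidates: Iterable[str],
                    vectors: Mapping[str, ContextVector],
                    k: int) -> NeighborList:
    """The k candidates with the most similar contexts to ``source``.

    The source itself (and any candidate whose normalized form equals it)
    is excluded; ties break lexicographically on the target term.
    """
    if source not in vectors:
        raise KeyError(f"source term {source!r} has no context vector")
    src = vectors[source]
    scored: list[tuple[float, str]] = []
    src_norm = " ".join(source.split()).lower()
    for cand in candidates:
        if cand == source or " ".join(cand.split()).lower() == src_norm:
            continue
        if cand not in vectors:
            continue
        scored.append((cosine(src, vectors[cand]), cand))
    scored.sort(key=lambda sc: (-sc[0], sc[1]))
    return NeighborList(source, tuple((t, s) for s, t in scored[:k]))


# ---------------------------------------------------------------------------
# source-term selection and inventory building
# ---------------------------------------------------------------------------

def select_source_terms(frequencies: Mapping[str, int],
                        thesaurus: Thesaurus | None,
                        config: DsmConfig) -> list[str]:
    """Pick source terms: strictly between the count bounds, optionally
    restricted to thesaurus members, ranked by frequency (ties
    lexicographic), truncated at ``n_sources``."""
    kept = [
        (t, c) for t, c in frequencies.items()
        if config.source_min_count < c < config.source_max_count
        and (thesaurus is None or t in thesaurus)
    ]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    return [t for t, _ in kept[:config.n_sources]]


def build_vectors(token_streams: Sequence[Sequence[Token]],
                  terms: Iterable[str],
                  config: DsmConfig,
                  vocabulary: Vocabulary) -> dict[str, ContextVector]:
    """Context vectors for ``terms`` under ``config.model``.

    SA counts every term (multi-word phrases included) as its own unit;
    BAM/BMM count only the constituent single words and compose. For
    single-word terms the three models coincide.
    """
    terms = sorted({" ".join(t.split()) for t in terms if t.strip()})
    if config.model == "SA":
        counts = count_contexts(token_streams, terms, config, vocabulary)
        return llr_weight(counts, "SA")
    constituents = sorted({w for t in terms for w in t.split()})
    counts = count_contexts(token_streams, constituents, config, vocabulary)
    singles = llr_weight(counts, config.model)
    compose = compose_bam if config.model == "BAM" else compose_bmm
    out: dict[str, ContextVector] = {}
    for term in terms:
        parts = [singles[w] for w in term.split()]
        vec = parts[0] if len(parts) == 1 else compose(parts)
        out[term] = ContextVector(term, config.model, vec.weights)
    return out


def build_inventory(docs: Sequence[Document],
                    source_terms: Iterable[str],
                    config: DsmConfig,
                    backend: LemmatizerBackend | None = None,
                    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
                    candidate_terms: Iterable[str] | None = None,
                    corpus_id: str = "",
                    ) -> TermInventory:
    """Full pipeline: preprocess -> count -> LLR -> compose -> top-k lists.

    The candidate target pool defaults to every single-word lexical unit
    with corpus frequency >= ``config.inventory_min_freq`` plus any
    multi-word source; an explicit ``candidate_terms`` pool (e.g. the
    output of an entity recognizer, or a thesaurus term list) can be
    supplied instead.
    """
    streams = [preprocess_text(d.text, backend) for d in docs]
    vocab = build_vocabulary(streams, config.cap, stopwords)
    sources = [term_key(t, backend) for t in source_terms]
    sources = [s for s in dict.fromkeys(sources) if s]
    if not sources:
        raise ValueError("no usable source terms")

    if candidate_terms is not None:
        pool = [term_key(t, backend) for t in candidate_terms]
        pool = [p for p in dict.fromkeys(pool) if p]
        freqs = term_frequencies(streams, pool, config.cross_sentence)
        candidates = sorted(p for p in pool
                            if freqs[p] >= config.inventory_min_freq)
    else:
        candidates = sorted(
            [lemma for lemma, c in vocab.units if c >= config.inventory_min_freq]
            + [s for s in sources if " " in s])

    all_terms = sorted(set(sources) | set(candidates))
    vectors = build_vectors(streams, all_terms, config, vocab)
    lists = {
        src: top_k_neighbors(src, candidates, vectors, config.k)
        for src in sources
    }
    provenance = {"config": asdict(config), "corpus": corpus_id,
                  "n_docs": len(docs), "n_candidates": len(candidates)}
    return TermInventory(lists, provenance)


def build_inventories_by_collection(docs: Sequence[Document], source_terms,
                                    config: DsmConfig, **kwargs,
                                    ) -> dict[str, TermInventory]:
    """Per-archive inventories (one per distinct ``Document.source``)."""
    out: dict[str, TermInventory] = {}
    for src_label in sorted({d.source for d in docs}):
        subset = [d for d in docs if d.source == src_label]
        out[src_label] = build_inventory(subset, source_terms, config,
                                         corpus_id=src_label, **kwargs)
    return out


def export_pairs(inventory: TermInventory, threshold: float = 0.8,
                 ) -> list[tuple[str, str, float]]:
    """All (source, target) pairs at cosine >= threshold (inclusive),
    deduplicated on the unordered pair keeping the maximum cosine."""
    best: dict[tuple[str, str], float] = {}
    for source, nlist in inventory:
        for target, sim in nlist.neighbors:
            if sim >= threshold:
                key = (source, target) if source <= target else (target, source)
                if sim > best.get(key, -1.0):
                    best[key] = sim
    return [(a, b, s) for (a, b), s in sorted(best.items())]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_vectors(vectors: Mapping[str, ContextVector], path: str | Path) -> None:
    """Delimited text vector store: term, model, then unit=weight pairs."""
    lines = []
    for term in sorted(vectors):
        vec = vectors[term]
        pairs = "\t".join(f"{u}={w!r}" for u, w in sorted(vec.weights.items()))
        lines.append(f"{term}\t{vec.model}" + (("\t" + pairs) if pairs else ""))
    Path(path).write_text("".join(l + "\n" for l in lines), "utf-8")


def read_vectors(path: str | Path) -> dict[str, ContextVector]:
    out: dict[str, ContextVector] = {}
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip():
            continue
        term, model, *pairs = line.split("\t")
        weights = {}
        for pair in pairs:
            unit, _, w = pair.rpartition("=")
            weights[unit] = float(w)
        out[term] = ContextVector(term, model, weights)
    return out


def write_inventory_tsv(inventory: TermInventory, path: str | Path) -> None:
    lines = ["source\trank\ttarget\tcosine"]
    for source in sorted(inventory.lists):
        for rank, (target, sim) in enumerate(inventory.lists[source].neighbors, 1):
            lines.append(f"{source}\t{rank}\t{target}\t{sim:.6f}")
    Path(path).write_text("".join(l + "\n" for l in lines), "utf-8")


def write_inventory_json(inventory: TermInventory, path: str | Path) -> None:
    payload = {
        "provenance": inventory.provenance,
        "lists": {s: [[t, sim] for t, sim in nl.neighbors]
                  for s, nl in inventory.lists.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", "utf-8")
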