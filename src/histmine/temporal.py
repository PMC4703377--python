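"""Term-usage timelines and decade partitioning.

Supports the diachronic side of the inventory: how often a term is used in
each year or decade, normalized to a rate per million tokens so that bins
with very different corpus volumes are comparable.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .corpus_io import Document
from .dsm import _Matcher, term_key
from .preprocess import LemmatizerBackend, preprocess_text, sentences
from .span_eval import decade_of

BINNINGS = ("year", "decade")


@dataclass(frozen=True)
class Timeline:
    """Usage series for one term: (bin, raw count, rate per million tokens)."""

    term: str
    binning: str
    series: tuple[tuple[int, int, float], ...]
    token_totals: tuple[tuple[int, int], ...]

    @property
    def total_count(self) -> int:
        return sum(c for _, c, _ in self.series)


def _bin_of(year: int, binning: str) -> int:
    return year if binning == "year" else year - year % 10


def term_timeline(docs: Sequence[Document], term: str,
                  binning: str = "decade", normalize: bool = True,
                  backend: LemmatizerBackend | None = None) -> Timeline:
    """Occurrence counts of ``term`` per time bin, zero-filled over the range.

    Occurrences are longest-match over lemma sequences; the rate is
    10^6 * count / tokens-in-bin (0 for empty bins). Documents without a
    year are skipped; if no document has a year this is an error.
    """
    if binning not in BINNINGS:
        raise ValueError(f"binning must be one of {BINNINGS}")
    key = term_key(term, backend)
    if not key:
        raise ValueError(f"term {term!r} normalizes to nothing")
    dated = [d for d in docs if d.year is not None]
    if not dated:
        raise ValueError("no document carries year metadata")
    matcher = _Matcher([key])
    counts: Counter[int] = Counter()
    tokens_per_bin: Counter[int] = Counter()
    for doc in dated:
        b = _bin_of(doc.year, binning)  # type: ignore[arg-type]
        stream = preprocess_text(doc.text, backend)
        word_count = sum(1 for t in stream if t.is_word)
        tokens_per_bin[b] += word_count
        for sent in sentences(stream):
            lemmas = [t.lemma for t in sent]
            counts[b] += len(matcher.scan(lemmas))
    lo = min(tokens_per_bin)
    hi = max(tokens_per_bin)
    step = 1 if binning == "year" else 10
    series = []
    totals = []
    for b in range(lo, hi + 1, step):
        c = counts.get(b, 0)
        n_tok = tokens_per_bin.get(b, 0)
        rate = 1e6 * c / n_tok if (normalize and n_tok) else (0.0 if normalize else float(c))
        series.append((b, c, rate))
        totals.append((b, n_tok))
    return Timeline(key, binning, tuple(series), tuple(totals))


def decade_partition(docs: Sequence[Document]) -> dict[str, list[Document]]:
    """Partition documents by decade; undated documents go to "unknown"."""
    buckets: dict[str, list[Document]] = defaultdict(list)
    for doc in docs:
        buckets[decade_of(doc.year)].append(doc)
    return dict(buckets)


def split_manifest(train_decades: Sequence[str], test_decade: str,
                   partition: dict[str, list[Document]],
                   ) -> tuple[list[str], list[str]]:
    """Train/test doc-id manifests for a train-on-decades/test-on-decade run."""
    if test_decade in train_decades:
        raise ValueError("test decade must not appear in the training decades")
    train = sorted(d.doc_id for dec in train_decades
                   for d in partition.get(dec, ()))
    test = sorted(d.doc_id for d in partition.get(test_decade, ()))
    return train, test


def write_timeline_tsv(timeline: Timeline, path: str | Path) -> None:
    lines = ["term\tbin\tcount\trate_per_million"]
    for b, c, rate in timeline.series:
        lines.append(f"{timeline.term}\t{b}\t{c}\t{rate:.4f}")
    Path(path).write_text("".join(l + "\n" for l in lines), "utf-8")
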