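"""Exact and relaxed span-match scoring, plus stratified k-fold splitting.

Used both for system-vs-gold entity evaluation and for inter-annotator
agreement (where one annotator's spans play the "gold" role; F is symmetric
under the swap). *Exact* requires identical offsets and category; *relaxed*
requires the category to agree and the character intervals to overlap by at
least one character, with one-to-one assignment greedy by overlap length.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .corpus_io import Document, EntitySpan

MATCH_MODES = ("exact", "relaxed")


@dataclass(frozen=True)
class CategoryScore:
    tp: int
    n_gold: int
    n_pred: int
    precision: float
    recall: float
    f_score: float


@dataclass
class MatchReport:
    """Per-category and micro-averaged overall P/R/F for one match mode."""

    mode: str
    per_category: dict[str, CategoryScore]
    overall: CategoryScore
    pairs: list[tuple[EntitySpan, EntitySpan]]  # (gold, pred), one-to-one
    degenerate: bool = False  # both sides empty


def _prf(tp: int, n_gold: int, n_pred: int) -> tuple[float, float, float]:
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


def match_spans(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan],
                mode: str) -> list[tuple[EntitySpan, EntitySpan]]:
    """One-to-one (gold, pred) match pairs under the given mode.

    Relaxed assignment is greedy by descending overlap length, ties broken
    by earlier gold start then earlier pred start.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"mode must be one of {MATCH_MODES}")
    if mode == "exact":
        index: dict[tuple, list[EntitySpan]] = defaultdict(list)
        for p in sorted(pred, key=lambda s: (s.doc_id, s.start, s.end)):
            index[(p.doc_id, p.start, p.end, p.category)].append(p)
        pairs = []
        for g in sorted(gold, key=lambda s: (s.doc_id, s.start, s.end)):
            bucket = index.get((g.doc_id, g.start, g.end, g.category))
            if bucket:
                pairs.append((g, bucket.pop(0)))
        return pairs

    candidates: list[tuple[int, int, int, int, int]] = []
    gold_sorted = sorted(gold, key=lambda s: (s.doc_id, s.start, s.end, s.category))
    pred_sorted = sorted(pred, key=lambda s: (s.doc_id, s.start, s.end, s.category))
    for gi, g in enumerate(gold_sorted):
        for pi, p in enumerate(pred_sorted):
            if g.category != p.category:
                continue
            ov = g.overlap(p)
            if ov >= 1:
                candidates.append((-ov, g.start, p.start, gi, pi))
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for _, _, _, gi, pi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        pairs.append((gold_sorted[gi], pred_sorted[pi]))
    return pairs


def prf_report(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan],
               mode: str) -> MatchReport:
    """Precision/recall/F per category plus micro-averaged totals.

    With both sides empty there is nothing to score; all metrics are
    reported as 1.0 and the report flagged degenerate.
    """
    if not gold and not pred:
        unit = CategoryScore(0, 0, 0, 1.0, 1.0, 1.0)
        return MatchReport(mode, {}, unit, [], degenerate=True)
    pairs = match_spans(gold, pred, mode)
    categories = sorted({s.category for s in gold} | {s.category for s in pred})
    per_category: dict[str, CategoryScore] = {}
    for cat in categories:
        tp = sum(1 for g, _ in pairs if g.category == cat)
        n_gold = sum(1 for s in gold if s.category == cat)
        n_pred = sum(1 for s in pred if s.category == cat)
        per_category[cat] = CategoryScore(tp, n_gold, n_pred,
                                          *_prf(tp, n_gold, n_pred))
    tp = len(pairs)
    overall = CategoryScore(tp, len(gold), len(pred),
                            *_prf(tp, len(gold), len(pred)))
    return MatchReport(mode, per_category, overall, pairs)


def write_match_report_tsv(reports: Mapping[str, MatchReport],
                           path: str | Path) -> None:
    """Category x {P, R, F} x mode table, mirroring the usual layout."""
    modes = list(reports)
    lines = ["category\tmetric\t" + "\t".join(modes)]
    cats = sorted({c for r in reports.values() for c in r.per_category})
    for cat in cats:
        for metric in ("precision", "recall", "f_score"):
            vals = []
            for m in modes:
                score = reports[m].per_category.get(cat)
                vals.append(f"{getattr(score, metric):.4f}" if score else "")
            lines.append(f"{cat}\t{metric}\t" + "\t".join(vals))
    for metric in ("precision", "recall", "f_score"):
        vals = [f"{getattr(reports[m].overall, metric):.4f}" for m in modes]
        lines.append(f"TOTAL\t{metric}\t" + "\t".join(vals))
    Path(path).write_text("".join(l + "\n" for l in lines), "utf-8")


# ---------------------------------------------------------------------------
# stratified k-fold splitting
# ---------------------------------------------------------------------------

def decade_of(year: int | None) -> str:
    """Decade label: floor(year / 10) * 10, or "unknown" without a year."""
    return "unknown" if year is None else str(year - year % 10)


def kfold_split(docs: Sequence[Document], k: int = 5, seed: int = 0,
                ) -> list[list[Document]]:
    """Split documents into k folds stratified by (source, decade).

    Within each stratum, documents are shuffled by the seed and dealt
    round-robin, so per-stratum fold sizes differ by at most one and every
    fold mixes archives and decades as evenly as the corpus allows.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(docs):
        raise ValueError(f"cannot split {len(docs)} documents into {k} folds")
    strata: dict[tuple[str, str], list[Document]] = defaultdict(list)
    for doc in docs:
        strata[(doc.source, decade_of(doc.year))].append(doc)
    folds: list[list[Document]] = [[] for _ in range(k)]
    offset = 0
    for key in sorted(strata):
        members = sorted(strata[key], key=lambda d: d.doc_id)
        random.Random(f"{seed}|{key[0]}|{key[1]}").shuffle(members)
        for i, doc in enumerate(members):
            folds[(offset + i) % k].append(doc)
        offset += len(members)
    return folds


def write_fold_manifest(folds: Sequence[Sequence[Document]],
                        path: str | Path) -> None:
    lines = ["doc_id\tfold"]
    for i, fold in enumerate(folds):
        for doc in sorted(fold, key=lambda d: d.doc_id):
            lines.append(f"{doc.doc_id}\t{i}")
    Path(path).write_text("".join(l + "\n" for l in lines), "utf-8")
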