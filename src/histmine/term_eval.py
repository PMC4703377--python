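"""Thesaurus-driven evaluation of neighbor lists and expert-judgment summaries.

Precision@k asks, per source term, whether *any* of its top-k related terms
is a thesaurus synonym; recall@k asks *how many* of the source's thesaurus
synonyms were found. Both are macro-averaged over source terms. Also here:
the nine-way relation-category summary with whole-percent shares, Cohen's
kappa for categorical agreement, and fuzzy linking of a historical
thesaurus onto a modern one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import edlib

from .corpus_io import Thesaurus, normalize_term
from .dsm import TermInventory

#: Fixed category order of the expert relation judgments. The first seven
#: constitute "semantically related"; the last two do not.
RELATION_CATEGORIES = (
    "Synonym",
    "isA",
    "isParent",
    "Affects",
    "isAffectedBy",
    "SpatiallyRelated",
    "OtherRelation",
    "Unrelated",
    "Non-disease pair",
)
N_RELATED = 7


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall at k = 1..k_max for one model's inventory."""

    model: str
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    n_sources: int
    n_excluded_precision: int
    n_excluded_recall: int

    @property
    def k_max(self) -> int:
        return len(self.precision)


@dataclass(frozen=True)
class RelationSummary:
    """Counts and whole-percent shares over the nine relation categories."""

    counts: Mapping[str, int]
    total: int
    percents: Mapping[str, int]
    related_count: int
    related_percent: int
    degenerate: bool  # all-zero input


def _round_half_away(x: float) -> int:
    """Round half away from zero (1.5 -> 2, -1.5 -> -2)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def _hits(nlist_targets: Sequence[str], thesaurus: Thesaurus, source: str,
          ) -> set[str]:
    syns = thesaurus.synonyms_of(source)
    return {t for t in nlist_targets if normalize_term(t) in syns}


def precision_at_k(inventory: TermInventory, thesaurus: Thesaurus,
                   k: int) -> float:
    """Fraction of sources with >= 1 thesaurus synonym in their top-k list.

    Sources absent from the thesaurus are excluded from the mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits, n = 0, 0
    for source, nlist in inventory:
        if source not in thesaurus:
            continue
        n += 1
        if _hits(nlist.targets(k), thesaurus, source):
            hits += 1
    return hits / n if n else 0.0


def recall_at_k(inventory: TermInventory, thesaurus: Thesaurus,
                k: int) -> float:
    """Mean fraction of each source's thesaurus synonyms found in its top-k.

    The denominator is *all* thesaurus synonyms of the source; sources with
    no synonyms (or absent from the thesaurus) are excluded from the mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total, n = 0.0, 0
    for source, nlist in inventory:
        syns = thesaurus.synonyms_of(source)
        if not syns:
            continue
        n += 1
        total += len(_hits(nlist.targets(k), thesaurus, source)) / len(syns)
    return total / n if n else 0.0


def pr_curve(inventory: TermInventory, thesaurus: Thesaurus,
             k_max: int = 20, model: str = "") -> PRCurve:
    """Precision and recall at every k from 1 to ``k_max``.

    Both series are monotone non-decreasing because top-k lists are nested.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n_p = sum(1 for s, _ in inventory if s in thesaurus)
    n_r = sum(1 for s, _ in inventory if thesaurus.synonyms_of(s))
    precision = tuple(precision_at_k(inventory, thesaurus, k)
                      for k in range(1, k_max + 1))
    recall = tuple(recall_at_k(inventory, thesaurus, k)
                   for k in range(1, k_max + 1))
    n_sources = len(inventory)
    return PRCurve(model or inventory.provenance.get("config", {}).get("model", ""),
                   precision, recall, n_sources,
                   n_sources - n_p, n_sources - n_r)


def write_pr_curve_tsv(curves: Sequence[PRCurve], path: str | Path) -> None:
    """Plot-ready long format: model, k, metric, value."""
    lines = ["model\tk\tmetric\tvalue"]
    for curve in curves:
        for k, (p, r) in enumerate(zip(curve.precision, curve.recall), 1):
            lines.append(f"{curve.model}\t{k}\tprecision\t{p:.6f}")
            lines.append(f"{curve.model}\t{k}\trecall\t{r:.6f}")
    Path(path).write_text("".join(l + "\n" for l in lines), "utf-8")


# ---------------------------------------------------------------------------
# expert relation judgments
# ---------------------------------------------------------------------------

def summarize_relations(counts: Mapping[str, int]) -> RelationSummary:
    """Totals and whole-percent shares for the nine relation categories.

    Percentages use round-half-away-from-zero on ``100 * count / total``;
    the aggregate "semantically related" share covers the first seven
    categories. An all-zero input is flagged degenerate with 0 shares.
    """
    full = {}
    for cat in RELATION_CATEGORIES:
        c = int(counts.get(cat, 0))
        if c < 0:
            raise ValueError(f"negative count for category {cat!r}")
        full[cat] = c
    unknown = set(counts) - set(RELATION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown relation categories: {sorted(unknown)}")
    total = sum(full.values())
    related = sum(full[c] for c in RELATION_CATEGORIES[:N_RELATED])
    if total == 0:
        return RelationSummary(full, 0, {c: 0 for c in full}, 0, 0, True)
    percents = {c: _round_half_away(100.0 * n / total) for c, n in full.items()}
    return RelationSummary(full, total, percents, related,
                           _round_half_away(100.0 * related / total), False)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    ``p_e`` comes from the product of the two raters' marginal label
    distributions. Perfect observed agreement returns 1.0 even when the
    chance term degenerates.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    if not labels_a:
        raise ValueError("label sequences must be non-empty")
    n = len(labels_a)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    if p_o == 1.0:
        return 1.0
    cats = set(labels_a) | set(labels_b)
    p_e = sum((sum(a == c for a in labels_a) / n)
              * (sum(b == c for b in labels_b) / n) for c in cats)
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# historical <-> modern thesaurus linking
# ---------------------------------------------------------------------------

@dataclass
class LinkResult:
    """Outcome of linking a historical thesaurus onto a modern one."""

    linked: list[tuple[str, str]]          # (historical concept, modern concept)
    unlinked_terms: set[str]               # historical terms with no counterpart
    unlinked_concepts: set[str]            # historical concepts with no link

    @property
    def n_linked(self) -> int:
        return len({h for h, _ in self.linked})


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def link_thesauri(historical: Thesaurus, modern: Thesaurus,
                  fuzzy: bool = True) -> LinkResult:
    """Link historical concepts to modern ones by shared or similar terms.

    A historical concept links to a modern concept when any of its terms
    equals, or (with ``fuzzy``) lies within a length-scaled Levenshtein
    distance of, any modern term: distance <= max(1, len(term) // 10).
    """
    modern_terms = sorted(modern.terms)
    linked: list[tuple[str, str]] = []
    matched_terms: set[str] = set()
    linked_concepts: set[str] = set()
    for h_cid in sorted(historical.entries):
        for term in sorted(historical.entries[h_cid]):
            partners: set[str] = set()
            if term in modern.terms:
                partners = modern.concepts_of(term)
            elif fuzzy:
                budget = max(1, len(term) // 10)
                for m in modern_terms:
                    if (abs(len(term) - len(m)) <= budget
                            and _edit_distance(term, m) <= budget):
                        partners |= modern.concepts_of(m)
            if partners:
                matched_terms.add(term)
                linked_concepts.add(h_cid)
                for m_cid in sorted(partners):
                    if (h_cid, m_cid) not in linked:
                        linked.append((h_cid, m_cid))
    unlinked_terms = historical.terms - matched_terms
    unlinked_concepts = set(historical.entries) - linked_concepts
    return LinkResult(linked, unlinked_terms, unlinked_concepts)


def write_relation_summary(summary: RelationSummary,
                           tsv_path: str | Path | None = None,
                           json_path: str | Path | None = None) -> None:
    if tsv_path is not None:
        lines = ["category\tcount\tpercent"]
        for cat in RELATION_CATEGORIES:
            lines.append(f"{cat}\t{summary.counts[cat]}\t{summary.percents[cat]}")
        lines.append(f"TOTAL SEMANTICALLY RELATED\t{summary.related_count}\t"
                     f"{summary.related_percent}")
        lines.append(f"TOTAL\t{summary.total}\t100")
        Path(tsv_path).write_text("".join(l + "\n" for l in lines), "utf-8")
    if json_path is not None:
        payload = {
            "counts": dict(summary.counts), "percents": dict(summary.percents),
            "total": summary.total, "related_count": summary.related_count,
            "related_percent": summary.related_percent,
            "degenerate": summary.degenerate,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n", "utf-8")
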