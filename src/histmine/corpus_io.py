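"""Reading and writing corpus artifacts.

Handles the external formats everything else consumes: plain-text document
collections with a TSV metadata table, brat standoff annotation files
(.ann paired with .txt), thesauri as delimited text, and annotation count
reports.

Character offsets follow the brat convention throughout: 0-based, end
exclusive, over unicode code points.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The seven entity categories of the historical-medicine annotation scheme.
ENTITY_CATEGORIES = (
    "Anatomical",
    "Biological_Entity",
    "Condition",
    "Environmental",
    "Sign_or_Symptom",
    "Subject",
    "Therapeutic_or_Investigational",
)

#: Legal participant roles per event type.
EVENT_ROLES = {
    "Affect": ("Cause", "Target", "Subj"),
    "Causality": ("Cause", "Result", "Subj"),
}


class BratFormatError(ValueError):
    """Raised when a brat standoff file violates the format contract."""


@dataclass(frozen=True)
class Document:
    """One corpus document with its archive provenance.

    Parameters
    ----------
    doc_id : unique identifier within a collection.
    source : archive label, e.g. ``"BMJ"`` or ``"MOH"``.
    year : calendar year CE, or ``None`` when unknown.
    text : full unicode document text (non-empty).
    """

    doc_id: str
    source: str
    year: int | None
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"document {self.doc_id!r} has empty text")
        if self.year is not None and not (1500 <= self.year <= 2100):
            raise ValueError(f"document {self.doc_id!r} has implausible year {self.year}")


@dataclass(frozen=True)
class EntitySpan:
    """A typed, text-bound annotation (brat T-line)."""

    span_id: str
    doc_id: str
    start: int
    end: int
    category: str
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"span {self.span_id!r}: invalid offsets [{self.start}, {self.end})"
            )

    def overlap(self, other: "EntitySpan") -> int:
        """Number of characters shared with ``other`` (0 if different docs)."""
        if self.doc_id != other.doc_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class EventRecord:
    """A trigger-anchored relationship (brat E-line): Affect or Causality."""

    event_id: str
    type: str
    trigger: EntitySpan
    participants: tuple[tuple[str, str], ...]  # ordered (role, reference)

    def __post_init__(self) -> None:
        if self.type not in EVENT_ROLES:
            raise ValueError(f"unknown event type {self.type!r}")
        legal = EVENT_ROLES[self.type]
        for role, _ in self.participants:
            if role not in legal:
                raise ValueError(
                    f"event {self.event_id!r}: role {role!r} illegal for {self.type}"
                )
        if not self.participants:
            raise ValueError(f"event {self.event_id!r} has no participants")


_WS = re.compile(r"\s+")


def normalize_term(term: str, fold_hyphens: bool = False) -> str:
    """Lowercase and collapse whitespace; optionally fold hyphens to spaces.

    Hyphen folding maps historical variants like ``cerebro-spinal fever``
    onto ``cerebro spinal fever``.
    """
    if fold_hyphens:
        term = term.replace("-", " ")
    return _WS.sub(" ", term.strip().lower())


@dataclass
class Thesaurus:
    """Concept -> synonym-set mapping (normalized terms).

    A term may belong to several concepts (lexical ambiguity is real:
    *consumption* the disease vs. *consumption* of food).
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    #: optional external category labels per term (labeled-lexicon column 3)
    term_categories: dict[str, set[str]] = field(default_factory=dict)
    #: rows rejected during parsing (blank terms)
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        self._by_term: dict[str, set[str]] = {}
        for cid, terms in self.entries.items():
            if not terms:
                raise ValueError(f"concept {cid!r} has no terms")
            for t in terms:
                self._by_term.setdefault(t, set()).add(cid)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self._by_term

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def terms(self) -> set[str]:
        return set(self._by_term)

    def concepts_of(self, term: str) -> set[str]:
        return set(self._by_term.get(normalize_term(term), ()))

    def synonyms_of(self, term: str) -> set[str]:
        """All co-concept terms of ``term``, excluding the term itself."""
        norm = normalize_term(term)
        out: set[str] = set()
        for cid in self._by_term.get(norm, ()):
            out |= self.entries[cid]
        out.discard(norm)
        return out

    def are_synonyms(self, a: str, b: str) -> bool:
        return bool(self.concepts_of(a) & self.concepts_of(b))


# ---------------------------------------------------------------------------
# document collections
# ---------------------------------------------------------------------------

def read_documents(text_dir: str | Path, metadata: str | Path) -> list[Document]:
    """Load a document collection from ``<doc_id>.txt`` files plus a metadata TSV.

    The metadata table (UTF-8, header row) must carry columns
    ``doc_id``, ``source``, ``year``; the year field may be empty.
    """
    text_dir = Path(text_dir)
    table = pd.read_csv(metadata, sep="\t", dtype=str, keep_default_na=False)
    for col in ("doc_id", "source", "year"):
        if col not in table.columns:
            raise ValueError(f"metadata table missing column {col!r}")
    docs: list[Document] = []
    seen: set[str] = set()
    for row in table.itertuples(index=False):
        doc_id = row.doc_id
        if doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc_id!r} in metadata")
        seen.add(doc_id)
        path = text_dir / f"{doc_id}.txt"
        if not path.is_file():
            raise FileNotFoundError(f"no text file for doc_id {doc_id!r}: {path}")
        year = int(row.year) if str(row.year).strip() else None
        docs.append(Document(doc_id, row.source, year, path.read_text("utf-8")))
    return docs


def write_documents(docs: Iterable[Document], text_dir: str | Path,
                    metadata: str | Path) -> None:
    """Inverse of :func:`read_documents` (one .txt per document plus TSV)."""
    text_dir = Path(text_dir)
    text_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in docs:
        (text_dir / f"{d.doc_id}.txt").write_text(d.text, "utf-8")
        rows.append({"doc_id": d.doc_id, "source": d.source,
                     "year": "" if d.year is None else str(d.year)})
    pd.DataFrame(rows, columns=["doc_id", "source", "year"]).to_csv(
        metadata, sep="\t", index=False)


# ---------------------------------------------------------------------------
# brat standoff
# ---------------------------------------------------------------------------

_TBOUND = re.compile(r"^(T[\w]+)\t(\S+) (\d+) (\d+)\t(.*)$")
_EVENT = re.compile(r"^(E[\w]+)\t(\S.*)$")


def read_brat(ann_path: str | Path, txt_path: str | Path,
              doc_id: str | None = None,
              ) -> tuple[list[EntitySpan], list[EventRecord]]:
    """Parse a brat ``.ann`` file against its paired ``.txt``.

    Text-bound (T) and event (E) lines are parsed; other line types
    (comments, attributes, relations) are ignored as pass-through. T-lines
    referenced as event triggers are returned inside their events, not in
    the entity list. Offsets and surfaces are validated against the text;
    discontinuous (semicolon-separated) spans are rejected.
    """
    ann_path, txt_path = Path(ann_path), Path(txt_path)
    text = txt_path.read_text("utf-8")
    if doc_id is None:
        doc_id = txt_path.stem

    spans: dict[str, EntitySpan] = {}
    raw_events: list[tuple[int, str, str]] = []
    for lineno, line in enumerate(ann_path.read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            fields = line.split("\t")
            if len(fields) > 1 and ";" in fields[1]:
                raise BratFormatError(
                    f"{ann_path.name}:{lineno}: discontinuous spans unsupported")
            m = _TBOUND.match(line)
            if m is None:
                raise BratFormatError(
                    f"{ann_path.name}:{lineno}: malformed text-bound line")
            tid, category, start, end, surface = m.groups()
            start, end = int(start), int(end)
            if end > len(text):
                raise BratFormatError(
                    f"{ann_path.name}:{lineno}: offset {end} beyond text "
                    f"length {len(text)}")
            slice_ = text[start:end]
            # brat replaces newlines with spaces in the surface column
            if slice_.replace("\n", " ") != surface:
                raise BratFormatError(
                    f"{ann_path.name}:{lineno}: surface {surface!r} does not "
                    f"match text slice {slice_!r}")
            spans[tid] = EntitySpan(tid, doc_id, start, end, category, slice_)
        elif line.startswith("E"):
            m = _EVENT.match(line)
            if m is None:
                raise BratFormatError(f"{ann_path.name}:{lineno}: malformed event line")
            raw_events.append((lineno, m.group(1), m.group(2)))

    events: list[EventRecord] = []
    trigger_ids: set[str] = set()
    known_ids = set(spans) | {eid for _, eid, _ in raw_events}
    for lineno, eid, body in raw_events:
        slots = body.split()
        etype, _, trig = slots[0].partition(":")
        if trig not in spans:
            raise BratFormatError(
                f"{ann_path.name}:{lineno}: trigger {trig!r} undefined")
        participants = []
        for slot in slots[1:]:
            role, _, ref = slot.partition(":")
            # brat numbers repeated roles Cause2, Cause3, ...
            base_role = role.rstrip("0123456789")
            if ref not in known_ids:
                raise BratFormatError(
                    f"{ann_path.name}:{lineno}: reference {ref!r} unresolved")
            participants.append((base_role, ref))
        trigger_ids.add(trig)
        try:
            events.append(EventRecord(eid, etype, spans[trig], tuple(participants)))
        except ValueError as exc:
            raise BratFormatError(f"{ann_path.name}:{lineno}: {exc}") from exc

    entities = [s for tid, s in spans.items() if tid not in trigger_ids]
    return entities, events


def write_brat(entities: Sequence[EntitySpan], events: Sequence[EventRecord],
               out_path: str | Path) -> Path:
    """Write annotations as a brat ``.ann`` file (identifiers renumbered).

    Round-trips through :func:`read_brat` up to identifier renumbering.
    """
    out_path = Path(out_path)
    lines: list[str] = []
    tid_of: dict[str, str] = {}
    counter = 0

    def emit_tbound(span: EntitySpan) -> str:
        nonlocal counter
        counter += 1
        new = f"T{counter}"
        tid_of[span.span_id] = new
        lines.append(f"{new}\t{span.category} {span.start} {span.end}\t"
                     f"{span.surface.replace(chr(10), ' ')}")
        return new

    for span in entities:
        emit_tbound(span)
    eid_of = {ev.event_id: f"E{i}" for i, ev in enumerate(events, 1)}
    for ev in events:
        trig = emit_tbound(ev.trigger)
        slots = [f"{ev.type}:{trig}"]
        role_seen: Counter[str] = Counter()
        for role, ref in ev.participants:
            if ref.startswith("E"):
                if ref not in eid_of:
                    raise ValueError(f"dangling event reference {ref!r}")
                new_ref = eid_of[ref]
            else:
                if ref not in tid_of:
                    raise ValueError(f"dangling span reference {ref!r}")
                new_ref = tid_of[ref]
            role_seen[role] += 1
            suffix = "" if role_seen[role] == 1 else str(role_seen[role])
            slots.append(f"{role}{suffix}:{new_ref}")
        lines.append(f"{eid_of[ev.event_id]}\t" + " ".join(slots))

    out_path.write_text("".join(line + "\n" for line in lines), "utf-8")
    return out_path


# ---------------------------------------------------------------------------
# thesauri
# ---------------------------------------------------------------------------

def read_thesaurus(path: str | Path, fold_hyphens: bool = False) -> Thesaurus:
    """Read a thesaurus TSV: ``concept_id<TAB>term[<TAB>external_category]``.

    Terms are normalized (lowercase, whitespace collapsed, optional hyphen
    folding); duplicates within a concept collapse; blank terms are rejected
    and counted.
    """
    entries: dict[str, set[str]] = {}
    categories: dict[str, set[str]] = {}
    rejected = 0
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        cid = parts[0].strip()
        term = normalize_term(parts[1], fold_hyphens) if len(parts) > 1 else ""
        if not cid or not term:
            rejected += 1
            continue
        entries.setdefault(cid, set()).add(term)
        if len(parts) > 2 and parts[2].strip():
            categories.setdefault(term, set()).add(parts[2].strip())
    return Thesaurus(entries, categories, rejected)


def write_thesaurus(thesaurus: Thesaurus, path: str | Path) -> None:
    lines = []
    for cid in sorted(thesaurus.entries):
        for term in sorted(thesaurus.entries[cid]):
            cats = sorted(thesaurus.term_categories.get(term, ()))
            extra = ("\t" + cats[0]) if cats else ""
            lines.append(f"{cid}\t{term}{extra}")
    Path(path).write_text("".join(line + "\n" for line in lines), "utf-8")


# ---------------------------------------------------------------------------
# annotation counting
# ---------------------------------------------------------------------------

def count_annotations(entities: Iterable[EntitySpan],
                      events: Iterable[EventRecord],
                      ) -> dict[str, dict[str, int]]:
    """Exact per-category entity counts and per-type event counts, with totals."""
    ecounts = Counter(e.category for e in entities)
    vcounts = Counter(ev.type for ev in events)
    return {
        "entities": {**dict(sorted(ecounts.items())), "TOTAL": sum(ecounts.values())},
        "events": {**dict(sorted(vcounts.items())), "TOTAL": sum(vcounts.values())},
    }


def write_count_report(counts: Mapping[str, Mapping[str, int]],
                       tsv_path: str | Path | None = None,
                       json_path: str | Path | None = None) -> None:
    if tsv_path is not None:
        lines = ["kind\tcategory\tcount"]
        for kind in ("entities", "events"):
            for cat, n in counts[kind].items():
                lines.append(f"{kind}\t{cat}\t{n}")
        Path(tsv_path).write_text("".join(l + "\n" for l in lines), "utf-8")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(counts, indent=2) + "\n", "utf-8")
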