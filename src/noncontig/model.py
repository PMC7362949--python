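"""Core data model for non-contiguous entity annotations.

A non-contiguous (discontiguous) entity is a mention composed of several
separated character spans that jointly identify one thing — e.g. the words
"skin" and "cancer" in the phrase "skin and lung cancer" together denote
the disease *skin cancer*.  Every entity here carries an ordered list of
one or more disjoint subspans; contiguous entities are simply the
single-subspan case.

Offsets are 0-based, half-open character (Unicode code point) intervals,
the PubAnnotation convention.  The structural rule enforced throughout is
that the subspans of a document form a *laminar family*: any two subspans
are either disjoint or one contains the other entirely.  Partial overlap
("breast cancer" and "cancer gene" inside "breast cancer gene") is a
violation; nesting ("breast cancer" and "cancer") is fine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

__all__ = [
    "Span",
    "Entity",
    "Relation",
    "AnnotatedDocument",
    "Violation",
    "ValidationError",
    "LookupError_",
    "spans_cross",
    "normalize_subspans",
    "validate_document",
    "covered_text",
]


class ValidationError(ValueError):
    """A structural constraint was breached where the API demands validity."""


class LookupError_(KeyError):
    """An entity or relation id was not found in the document."""


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[begin, end)``; empty spans are invalid."""

    begin: int
    end: int

    def __post_init__(self) -> None:
        if self.begin < 0 or self.end <= self.begin:
            raise ValidationError(
                f"invalid span ({self.begin}, {self.end}): need 0 <= begin < end"
            )

    def __len__(self) -> int:
        return self.end - self.begin

    def contains(self, other: "Span") -> bool:
        return self.begin <= other.begin and other.end <= self.end

    def contains_offset(self, position: int) -> bool:
        return self.begin <= position < self.end

    def overlaps(self, other: "Span") -> bool:
        return self.begin < other.end and other.begin < self.end


def spans_cross(a: Span, b: Span) -> bool:
    """True iff *a* and *b* overlap partially (neither contains the other).

    Crossing pairs are the configurations the laminar constraint forbids;
    containment and disjointness (including touching half-open intervals,
    e.g. ``(0,5)`` and ``(5,9)``) are allowed.
    """
    return a.overlaps(b) and not a.contains(b) and not b.contains(a)


def normalize_subspans(spans: Sequence[Span]) -> tuple[Span, ...]:
    """Canonicalize a subspan list: sort by begin, merge overlaps and adjacency.

    The result is the unique sorted tuple of pairwise disjoint, non-adjacent
    spans covering the same characters.  Idempotent.  Raises
    :class:`ValidationError` on an empty input.
    """
    if not spans:
        raise ValidationError("an entity needs at least one subspan")
    ordered = sorted(spans)
    merged: list[Span] = [ordered[0]]
    for span in ordered[1:]:
        last = merged[-1]
        if span.begin <= last.end:  # overlap or adjacency
            if span.end > last.end:
                merged[-1] = Span(last.begin, span.end)
        else:
            merged.append(span)
    return tuple(merged)


@dataclass(frozen=True)
class Entity:
    """An annotation: id, type label, and an ordered list of disjoint subspans.

    Subspans are normalized on construction, so two entities covering the
    same characters compare equal regardless of input order or redundancy.
    """

    id: str
    label: str
    subspans: tuple[Span, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subspans", normalize_subspans(self.subspans))

    @property
    def is_contiguous(self) -> bool:
        return len(self.subspans) == 1

    @property
    def begin(self) -> int:
        return self.subspans[0].begin

    @property
    def end(self) -> int:
        return self.subspans[-1].end

    def covered_length(self) -> int:
        return sum(len(s) for s in self.subspans)


@dataclass(frozen=True)
class Relation:
    """A typed, directed link between two entities of the same document."""

    id: str
    predicate: str
    subject: str
    object: str


@dataclass(frozen=True)
class Violation:
    """One breached structural constraint, reported rather than raised."""

    kind: str  # "crossing" | "out_of_bounds" | "dangling_relation" | "duplicate_id"
    message: str
    ids: tuple[str, ...] = ()


@dataclass
class AnnotatedDocument:
    """Text plus entities, relations and pass-through attributes.

    ``attributes`` are opaque records (PubAnnotation ``attributes`` blocks)
    preserved verbatim apart from re-pointing of entity references during
    representation conversion.  ``sections`` optionally names regions of the
    text (e.g. ``title`` / ``abstract`` for PubTator input) and is carried
    for reporting only — it does not take part in structural equality.
    """

    text: str
    source_db: str = ""
    source_id: str = ""
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    attributes: list[dict[str, Any]] = field(default_factory=list)
    sections: dict[str, Span] = field(default_factory=dict)

    # -- lookup helpers -------------------------------------------------

    def entity(self, entity_id: str) -> Entity:
        for e in self.entities:
            if e.id == entity_id:
                return e
        raise LookupError_(f"no entity with id {entity_id!r}")

    def has_entity(self, entity_id: str) -> bool:
        return any(e.id == entity_id for e in self.entities)

    def replace_entity(self, entity_id: str, new: Entity) -> None:
        for i, e in enumerate(self.entities):
            if e.id == entity_id:
                self.entities[i] = new
                return
        raise LookupError_(f"no entity with id {entity_id!r}")

    def all_subspans(self) -> Iterator[tuple[Entity, Span]]:
        for e in self.entities:
            for s in e.subspans:
                yield e, s

    def section_of(self, position: int) -> str:
        for name, span in self.sections.items():
            if span.contains_offset(position):
                return name
        return "body"

    def copy(self) -> "AnnotatedDocument":
        return AnnotatedDocument(
            text=self.text,
            source_db=self.source_db,
            source_id=self.source_id,
            entities=list(self.entities),
            relations=list(self.relations),
            attributes=[dict(a) for a in self.attributes],
            sections=dict(self.sections),
        )

    def structurally_equal(self, other: "AnnotatedDocument") -> bool:
        """Equality on text and annotation content, ignoring sections."""
        return (
            self.text == other.text
            and self.source_db == other.source_db
            and self.source_id == other.source_id
            and self.entities == other.entities
            and self.relations == other.relations
            and self.attributes == other.attributes
        )


def validate_document(doc: AnnotatedDocument) -> list[Violation]:
    """Check every structural invariant; return one record per breach.

    Checked: unique entity/relation ids, subspans inside ``[0, len(text))``,
    relation endpoints resolving to entities, and the laminar constraint
    over the subspans of *all* entities (a crossing pair is reported once).
    An empty list means the document is valid.
    """
    violations: list[Violation] = []

    seen: set[str] = set()
    for e in doc.entities:
        if e.id in seen:
            violations.append(
                Violation("duplicate_id", f"duplicate entity id {e.id!r}", (e.id,))
            )
        seen.add(e.id)
    rseen: set[str] = set()
    for r in doc.relations:
        if r.id in rseen:
            violations.append(
                Violation("duplicate_id", f"duplicate relation id {r.id!r}", (r.id,))
            )
        rseen.add(r.id)

    n = len(doc.text)
    for e in doc.entities:
        for s in e.subspans:
            if s.end > n:
                violations.append(
                    Violation(
                        "out_of_bounds",
                        f"entity {e.id!r} subspan ({s.begin}, {s.end}) exceeds "
                        f"text length {n}",
                        (e.id,),
                    )
                )

    for r in doc.relations:
        for endpoint in (r.subject, r.object):
            if not doc.has_entity(endpoint):
                violations.append(
                    Violation(
                        "dangling_relation",
                        f"relation {r.id!r} references missing entity {endpoint!r}",
                        (r.id, endpoint),
                    )
                )

    flat = list(doc.all_subspans())
    flat.sort(key=lambda pair: (pair[1].begin, -pair[1].end))
    # sweep: compare each span against currently open ones only
    open_stack: list[tuple[Entity, Span]] = []
    for e, s in flat:
        while open_stack and open_stack[-1][1].end <= s.begin:
            open_stack.pop()
        for oe, os_ in open_stack:
            if spans_cross(os_, s):
                violations.append(
                    Violation(
                        "crossing",
                        f"subspan ({s.begin}, {s.end}) of entity {e.id!r} crosses "
                        f"({os_.begin}, {os_.end}) of entity {oe.id!r}",
                        (oe.id, e.id),
                    )
                )
        open_stack.append((e, s))

    return violations


def covered_text(doc: AnnotatedDocument, entity: Entity | str) -> str:
    """The entity's surface form: subspan texts in order, space-joined.

    For ``[(0,4), (14,20)]`` over "skin and lung cancer" this is
    "skin cancer" — the reading a human gives the non-contiguous mention.
    """
    e = doc.entity(entity) if isinstance(entity, str) else entity
    if isinstance(entity, Entity) and not any(x is entity or x == entity for x in doc.entities):
        raise LookupError_(f"entity {entity.id!r} does not belong to this document")
    return " ".join(doc.text[s.begin : s.end] for s in e.subspans)
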