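"""PubAnnotation / PubTator I/O and chaining-representation conversion.

PubAnnotation JSON stores entity annotations as *denotations*.  Two span
dialects are in the wild: a single span object ``{"begin": b, "end": e}``
for contiguous entities, and a list of such objects for non-contiguous
ones.  Both are read; writing defaults to the backward-compatible dialect
(a list only when there are multiple subspans).

The *chaining representation* is the legacy encoding of a non-contiguous
entity: each subspan becomes its own contiguous entity, the extra ones are
typed ``_FRAGMENT``, and the pieces are tied together with relations whose
predicate is ``_lexicallyChainedTo``.  :func:`chain_to_multispan` collapses
those chains into native multi-subspan entities and
:func:`multispan_to_chain` re-emits them; the two are mutually inverse up
to generated identifiers.

PubTator is the pipe/tab text format used by PubTator Central:
``PMID|t|title`` and ``PMID|a|abstract`` lines followed by tab-separated
annotation rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, IO

from .model import (
    AnnotatedDocument,
    Entity,
    Relation,
    Span,
    ValidationError,
    normalize_subspans,
    validate_document,
)

__all__ = [
    "FormatError",
    "ConversionError",
    "ChainDirection",
    "ChainConfig",
    "MultispanStyle",
    "Dialect",
    "parse_pubannotation",
    "serialize_pubannotation",
    "chain_to_multispan",
    "multispan_to_chain",
    "parse_pubtator",
]

DEFAULT_FRAGMENT_LABEL = "_FRAGMENT"
DEFAULT_CHAIN_PREDICATE = "_lexicallyChainedTo"


class FormatError(ValueError):
    """Malformed input file (bad JSON structure, bad offsets, bad rows)."""


class ConversionError(ValueError):
    """A chain is ill-formed (cyclic, or not exactly one labeled member)."""


class ChainDirection(Enum):
    FRAGMENT_AS_SUBJECT = "fragment_as_subject"
    FRAGMENT_AS_OBJECT = "fragment_as_object"


@dataclass(frozen=True)
class ChainConfig:
    fragment_label: str = DEFAULT_FRAGMENT_LABEL
    chain_predicate: str = DEFAULT_CHAIN_PREDICATE
    direction: ChainDirection = ChainDirection.FRAGMENT_AS_SUBJECT

    def __post_init__(self) -> None:
        if not self.fragment_label or not self.chain_predicate:
            raise ValidationError("fragment_label and chain_predicate must be non-empty")


class MultispanStyle(Enum):
    LIST_ONLY_WHEN_MULTIPLE = "list_only_when_multiple"
    ALWAYS_LIST = "always_list"


@dataclass(frozen=True)
class Dialect:
    multispan_style: MultispanStyle = MultispanStyle.LIST_ONLY_WHEN_MULTIPLE


# ---------------------------------------------------------------------------
# PubAnnotation JSON
# ---------------------------------------------------------------------------

def _parse_span_obj(obj: Any, den_id: str, text_len: int) -> Span:
    if not isinstance(obj, dict) or "begin" not in obj or "end" not in obj:
        raise FormatError(f"denotation {den_id!r}: span must have begin/end")
    begin, end = obj["begin"], obj["end"]
    if not isinstance(begin, int) or not isinstance(end, int) or end <= begin or begin < 0:
        raise FormatError(f"denotation {den_id!r}: invalid span ({begin}, {end})")
    if end > text_len:
        raise FormatError(
            f"denotation {den_id!r}: span ({begin}, {end}) exceeds text length {text_len}"
        )
    return Span(begin, end)


def parse_pubannotation(source: str | bytes | dict | IO[str]) -> AnnotatedDocument:
    """Parse one PubAnnotation JSON document (either span dialect).

    Accepts a JSON string/bytes, an already-decoded dict, or a text file
    object.  Every denotation becomes an :class:`Entity`; relations and
    attributes are preserved.  Raises :class:`FormatError` on a missing
    ``text`` field or an offset outside the text, naming the denotation.
    """
    if isinstance(source, (str, bytes)):
        data = json.loads(source)
    elif isinstance(source, dict):
        data = source
    else:
        data = json.load(source)
    if not isinstance(data, dict) or "text" not in data:
        raise FormatError("PubAnnotation document must be an object with a 'text' field")
    text = data["text"]
    if not isinstance(text, str):
        raise FormatError("'text' must be a string")

    entities: list[Entity] = []
    for den in data.get("denotations", []) or []:
        den_id = str(den.get("id", "?"))
        span = den.get("span")
        if isinstance(span, list):
            if not span:
                raise FormatError(f"denotation {den_id!r}: empty span list")
            subspans = [_parse_span_obj(s, den_id, len(text)) for s in span]
        else:
            subspans = [_parse_span_obj(span, den_id, len(text))]
        entities.append(Entity(den_id, str(den.get("obj", "")), tuple(subspans)))

    relations = [
        Relation(
            str(r.get("id", f"R{i}")),
            str(r.get("pred", "")),
            str(r.get("subj", "")),
            str(r.get("obj", "")),
        )
        for i, r in enumerate(data.get("relations", []) or [])
    ]
    attributes = [dict(a) for a in data.get("attributes", []) or []]
    return AnnotatedDocument(
        text=text,
        source_db=str(data.get("sourcedb", "")),
        source_id=str(data.get("sourceid", "")),
        entities=entities,
        relations=relations,
        attributes=attributes,
    )


def serialize_pubannotation(
    doc: AnnotatedDocument, dialect: Dialect = Dialect()
) -> dict[str, Any]:
    """Serialize to a PubAnnotation JSON object (round-trips with parse).

    Under the default dialect a single-subspan entity emits a plain span
    object and a multi-subspan entity a span list; ``ALWAYS_LIST`` emits a
    list unconditionally.  The document must be valid.
    """
    violations = validate_document(doc)
    if violations:
        raise ValidationError(
            "cannot serialize invalid document: " + "; ".join(v.message for v in violations)
        )
    out: dict[str, Any] = {"text": doc.text}
    if doc.source_db:
        out["sourcedb"] = doc.source_db
    if doc.source_id:
        out["sourceid"] = doc.source_id
    denotations = []
    for e in doc.entities:
        spans = [{"begin": s.begin, "end": s.end} for s in e.subspans]
        if (
            dialect.multispan_style is MultispanStyle.LIST_ONLY_WHEN_MULTIPLE
            and len(spans) == 1
        ):
            span_field: Any = spans[0]
        else:
            span_field = spans
        denotations.append({"id": e.id, "span": span_field, "obj": e.label})
    if denotations:
        out["denotations"] = denotations
    if doc.relations:
        out["relations"] = [
            {"id": r.id, "pred": r.predicate, "subj": r.subject, "obj": r.object}
            for r in doc.relations
        ]
    if doc.attributes:
        out["attributes"] = [dict(a) for a in doc.attributes]
    return out


# ---------------------------------------------------------------------------
# chaining representation <-> native multi-span
# ---------------------------------------------------------------------------

def chain_to_multispan(
    doc: AnnotatedDocument, cfg: ChainConfig = ChainConfig()
) -> AnnotatedDocument:
    """Collapse fragment chains into native multi-subspan entities.

    Entities connected (transitively) by relations with the chain predicate
    merge into one entity whose subspans are the normalized union of all
    members' subspans and whose id and label come from the unique member
    not typed as a fragment.  Chain relations and fragment entities are
    removed; attributes and other relations pointing at a collapsed
    fragment are re-pointed to the merged entity.  A document with no chain
    relations is returned unchanged (as a copy).
    """
    chain_rels = [r for r in doc.relations if r.predicate == cfg.chain_predicate]
    if not chain_rels:
        return doc.copy()

    # union-find over entity ids mentioned in chain relations
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for r in chain_rels:
        for endpoint in (r.subject, r.object):
            if not doc.has_entity(endpoint):
                raise ConversionError(
                    f"chain relation {r.id!r} references missing entity {endpoint!r}"
                )
        union(r.subject, r.object)

    components: dict[str, list[str]] = {}
    for x in parent:
        components.setdefault(find(x), []).append(x)
    edge_count: dict[str, int] = {}
    for r in chain_rels:
        root = find(r.subject)
        edge_count[root] = edge_count.get(root, 0) + 1

    id_map: dict[str, str] = {}  # fragment id -> merged entity id
    merged: dict[str, Entity] = {}  # representative id -> merged entity
    removed: set[str] = set()
    for root, member_ids in components.items():
        if edge_count.get(root, 0) >= len(member_ids):
            raise ConversionError(
                f"cyclic chain involving entities {sorted(member_ids)}"
            )
        members = [doc.entity(i) for i in member_ids]
        labeled = [e for e in members if e.label != cfg.fragment_label]
        if len(labeled) != 1:
            raise ConversionError(
                f"chain {sorted(member_ids)} must have exactly one non-fragment "
                f"member, found {len(labeled)}"
            )
        head = labeled[0]
        subspans = normalize_subspans(
            [s for e in members for s in e.subspans]
        )
        merged[head.id] = Entity(head.id, head.label, subspans)
        for e in members:
            removed.add(e.id)
            id_map[e.id] = head.id

    entities: list[Entity] = []
    for e in doc.entities:
        if e.id in removed:
            if e.id in merged:
                entities.append(merged[e.id])
        else:
            entities.append(e)
    chain_rel_ids = {r.id for r in chain_rels}
    relations = [
        Relation(r.id, r.predicate, id_map.get(r.subject, r.subject), id_map.get(r.object, r.object))
        for r in doc.relations
        if r.id not in chain_rel_ids
    ]
    attributes = []
    for a in doc.attributes:
        a = dict(a)
        if a.get("subj") in id_map:
            a["subj"] = id_map[a["subj"]]
        attributes.append(a)
    return AnnotatedDocument(
        text=doc.text,
        source_db=doc.source_db,
        source_id=doc.source_id,
        entities=entities,
        relations=relations,
        attributes=attributes,
        sections=dict(doc.sections),
    )


def multispan_to_chain(
    doc: AnnotatedDocument, cfg: ChainConfig = ChainConfig()
) -> AnnotatedDocument:
    """Re-emit multi-subspan entities in the legacy chaining representation.

    An entity with k > 1 subspans becomes k contiguous entities: the last
    subspan (in text order) keeps the original id and label, the earlier
    ones get the fragment label and derived ids, and k-1 chain relations
    link consecutive pieces.  Inverse of :func:`chain_to_multispan`.
    """
    for e in doc.entities:
        if e.label == cfg.fragment_label:
            raise ConversionError(
                f"entity {e.id!r} already carries the fragment label "
                f"{cfg.fragment_label!r}; document is already chained"
            )
    entities: list[Entity] = []
    relations: list[Relation] = list(doc.relations)
    existing_rel_ids = {r.id for r in relations}
    for e in doc.entities:
        if e.is_contiguous:
            entities.append(e)
            continue
        k = len(e.subspans)
        pieces: list[Entity] = []
        for i, s in enumerate(e.subspans):
            if i == k - 1:
                pieces.append(Entity(e.id, e.label, (s,)))
            else:
                pieces.append(Entity(f"{e.id}-F{i + 1}", cfg.fragment_label, (s,)))
        entities.extend(pieces)
        for i in range(k - 1):
            rid = f"R-{e.id}-{i + 1}"
            while rid in existing_rel_ids:
                rid = rid + "x"
            existing_rel_ids.add(rid)
            frag, nxt = pieces[i].id, pieces[i + 1].id
            if cfg.direction is ChainDirection.FRAGMENT_AS_SUBJECT:
                relations.append(Relation(rid, cfg.chain_predicate, frag, nxt))
            else:
                relations.append(Relation(rid, cfg.chain_predicate, nxt, frag))
    return AnnotatedDocument(
        text=doc.text,
        source_db=doc.source_db,
        source_id=doc.source_id,
        entities=entities,
        relations=relations,
        attributes=[dict(a) for a in doc.attributes],
        sections=dict(doc.sections),
    )


# ---------------------------------------------------------------------------
# PubTator
# ---------------------------------------------------------------------------

def parse_pubtator(source: str | IO[str]) -> list[AnnotatedDocument]:
    """Parse PubTator pipe/tab records into documents.

    Document text is ``title + "\\n" + abstract``; annotation rows become
    contiguous entities carrying the concept id in an attribute record.
    The title/abstract boundary is recorded in ``sections`` for reporting.
    A mention string that disagrees with the text at its offsets raises
    :class:`FormatError` naming the line.
    """
    if not isinstance(source, str):
        source = source.read()
    docs: list[AnnotatedDocument] = []
    title: str | None = None
    abstract: str = ""
    pmid: str | None = None
    annotations: list[tuple[int, int, int, str, str, str]] = []

    def flush() -> None:
        nonlocal title, abstract, pmid, annotations
        if pmid is None:
            return
        text = (title or "") + ("\n" + abstract if abstract else "")
        sections = {}
        if title:
            sections["title"] = Span(0, len(title))
        if abstract:
            sections["abstract"] = Span(len(title or "") + 1, len(text))
        entities = []
        for i, (lineno, start, end, mention, etype, concept) in enumerate(annotations):
            if text[start:end] != mention:
                raise FormatError(
                    f"line {lineno}: mention {mention!r} does not match text "
                    f"{text[start:end]!r} at ({start}, {end})"
                )
            entities.append(Entity(f"T{i + 1}", etype, (Span(start, end),)))
        attributes = [
            {"id": f"A{i + 1}", "subj": f"T{i + 1}", "pred": "concept", "obj": concept}
            for i, (_, _, _, _, _, concept) in enumerate(annotations)
            if concept
        ]
        docs.append(
            AnnotatedDocument(
                text=text,
                source_db="PubMed",
                source_id=pmid,
                entities=entities,
                attributes=attributes,
                sections=sections,
            )
        )
        title, abstract, pmid, annotations = None, "", None, []

    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            flush()
            continue
        if "|t|" in line or "|a|" in line:
            doc_id, kind, payload = line.split("|", 2)
            if pmid is not None and doc_id != pmid:
                flush()
            pmid = doc_id
            if kind == "t":
                title = payload
            elif kind == "a":
                abstract = payload
            else:
                raise FormatError(f"line {lineno}: unknown section code {kind!r}")
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(f"line {lineno}: expected tab-separated annotation row")
        doc_id = fields[0]
        if pmid is not None and doc_id != pmid:
            flush()
            raise FormatError(
                f"line {lineno}: annotation for {doc_id!r} outside its document block"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer offsets") from exc
        mention, etype = fields[3], fields[4]
        concept = fields[5] if len(fields) > 5 else ""
        annotations.append((lineno, start, end, mention, etype, concept))
    flush()
    return docs
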