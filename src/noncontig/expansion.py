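"""Rule-based mining of non-contiguous entities from coordination lists.

Biomedical text elides shared head words in lists: in "prostate, lung,
colorectal and breast cancers" only the final member ("breast cancers")
is fully written, and automatic taggers typically annotate only that
final member.  The earlier members (*prostate cancers*, *lung cancers*,
*colorectal cancers*) exist in the text as separated fragments — the
modifier plus the shared head — i.e. as non-contiguous entities.

The miner recovers them with a dictionary-matching rule:

1. find a tagged entity immediately preceded by a coordinating trigger
   (the word "and", or a slash in ``methicillin/oxacillin resistance``
   style lists);
2. scan leftward over delimiter-separated word groups (commas, slashes,
   interior "and");
3. for each group, substitute it for a leading prefix of the tagged
   *anchor* term and look the resulting phrase up in a lexicon; a hit
   yields a new multi-subspan entity made of the group's fragment plus
   the shared tail of the anchor.

Matching is case-insensitive with optional plural folding, so "prostate"
+ "cancers" matches a lexicon entry "prostate cancer" while the surface
form keeps the plural.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

from .model import AnnotatedDocument, Entity, Span, spans_cross, normalize_subspans

__all__ = [
    "LexiconError",
    "Lexicon",
    "Token",
    "tokenize",
    "MinerConfig",
    "CandidateList",
    "ExpandedMention",
    "load_lexicon",
    "substitute_and_match",
    "detect_candidate_lists",
    "expand_document",
    "summarize_counts",
]


class LexiconError(ValueError):
    """Malformed lexicon input (bad row)."""


_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return _WS.sub(" ", term.strip()).lower()


def _fold_plural(term: str) -> str | None:
    """Singular variant obtained by stripping a terminal 's' (or 'es' is
    left to the plain 's' rule); None when not applicable."""
    if term.endswith("s") and not term.endswith("ss") and len(term) > 3:
        return term[:-1]
    return None


@dataclass
class Lexicon:
    """Normalized term -> set of (concept id, entity type).

    Lookup is exact on the normalized string, with an optional fallback
    that strips a terminal plural 's' from the last word.
    """

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    plural_folding: bool = True

    def add(self, concept_id: str, entity_type: str, synonym: str) -> None:
        key = normalize_term(synonym)
        if key:
            self.entries.setdefault(key, set()).add((concept_id, entity_type))

    def lookup(self, term: str) -> set[tuple[str, str]]:
        key = normalize_term(term)
        hit = self.entries.get(key)
        if hit:
            return hit
        if self.plural_folding:
            singular = _fold_plural(key)
            if singular is not None:
                return self.entries.get(singular, set())
        return set()

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self) -> str:
        lines = []
        for term in sorted(self.entries):
            for concept_id, etype in sorted(self.entries[term]):
                lines.append(f"{concept_id}\t{etype}\t{term}")
        return "\n".join(lines) + ("\n" if lines else "")


def load_lexicon(source: str | IO[str], plural_folding: bool = True) -> Lexicon:
    """Read a TSV lexicon: one ``concept_id<TAB>entity_type<TAB>synonym`` row
    per line.  Duplicate synonyms union their concept sets.  A row without
    three fields raises :class:`LexiconError` with its line number.
    """
    if not isinstance(source, str):
        source = source.read()
    lex = Lexicon(plural_folding=plural_folding)
    for lineno, raw in enumerate(source.splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise LexiconError(f"line {lineno}: expected 3 tab-separated fields")
        concept_id, etype, synonym = fields[0], fields[1], fields[2]
        lex.add(concept_id, etype, synonym)
    return lex


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    text: str
    begin: int
    end: int

    @property
    def is_delimiter_char(self) -> bool:
        return self.text in {",", "/"}


_TOKEN_RE = re.compile(r"[0-9A-Za-z](?:[0-9A-Za-z-]*[0-9A-Za-z])?|[,/]")

# characters between tokens that end a sentence / clause for list scanning
_BOUNDARY_RE = re.compile(r"[.;:!?()\[\]\n]")


def tokenize(text: str) -> list[Token]:
    """Words (maximal runs of letters/digits/hyphens) and the delimiter
    characters ``,`` and ``/``, each with exact character offsets."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinerConfig:
    """Knobs of the coordination-list miner.

    ``trigger_word`` is the coordinating conjunction that marks the final
    list member; ``delimiters`` separate earlier members; the leftward
    scan stops at a sentence boundary, after ``max_items`` groups, or (by
    default) at the first group producing no lexicon match.
    ``list_introducers`` are quantifier-like words ("both A and B") that
    mark the left edge of a list and are never part of a member.
    """

    trigger_word: str = "and"
    delimiters: frozenset[str] = frozenset({",", "/", "and"})
    max_items: int = 10
    stop_on_unmatched: bool = True
    plural_folding: bool = True
    slash_lists: bool = True
    list_introducers: frozenset[str] = frozenset({"both", "either", "neither", "including"})

    def __post_init__(self) -> None:
        if self.max_items < 1:
            raise ValueError("max_items must be >= 1")


@dataclass(frozen=True)
class ListItem:
    """One delimiter-separated token group preceding the anchor."""

    tokens: tuple[Token, ...]

    @property
    def begin(self) -> int:
        return self.tokens[0].begin

    @property
    def end(self) -> int:
        return self.tokens[-1].end


@dataclass(frozen=True)
class CandidateList:
    """A tagged final entity plus the word groups scanned leftward of it."""

    anchor: Entity
    anchor_tokens: tuple[Token, ...]
    items: tuple[ListItem, ...]  # ordered left-to-right in the text
    delimiters: tuple[str, ...]


def _is_delim(tok: Token, cfg: MinerConfig) -> bool:
    if tok.text == ",":
        return True
    if tok.text == "/":
        return cfg.slash_lists or "/" in cfg.delimiters
    return tok.text.lower() == cfg.trigger_word or tok.text.lower() in {
        d for d in cfg.delimiters if d.isalpha()
    }


def detect_candidate_lists(
    doc: AnnotatedDocument, cfg: MinerConfig = MinerConfig()
) -> list[CandidateList]:
    """Find tagged entities that terminate a coordination list.

    A contiguous tagged entity immediately preceded (across whitespace
    only) by the trigger word — or by a slash when slash lists are on —
    anchors a candidate.  Earlier members are collected leftward as
    delimiter-separated token groups, stopping at a sentence boundary, a
    list introducer, or ``max_items`` groups.
    """
    tokens = tokenize(doc.text)
    candidates: list[CandidateList] = []
    for entity in doc.entities:
        if not entity.is_contiguous:
            continue
        span = entity.subspans[0]
        anchor_tokens = tuple(
            t for t in tokens if t.begin >= span.begin and t.end <= span.end
        )
        if not anchor_tokens:
            continue
        # token immediately before the anchor, with only whitespace between
        prev_idx = None
        for i, t in enumerate(tokens):
            if t.begin >= span.begin:
                break
            prev_idx = i
        if prev_idx is None:
            continue
        prev = tokens[prev_idx]
        gap = doc.text[prev.end : span.begin]
        if _BOUNDARY_RE.search(gap):
            continue
        is_and = prev.text.lower() == cfg.trigger_word
        is_slash = prev.text == "/" and cfg.slash_lists
        if not (is_and or is_slash):
            continue
        if is_and and gap.strip():
            continue  # something other than whitespace between "and" and anchor

        items: list[ListItem] = []
        delims: list[str] = [prev.text]
        group: list[Token] = []
        i = prev_idx - 1
        stopped = False
        while i >= 0 and len(items) < cfg.max_items and not stopped:
            tok = tokens[i]
            right = tokens[i + 1]
            between = doc.text[tok.end : right.begin]
            if _BOUNDARY_RE.search(between):
                break  # sentence/clause boundary
            if _is_delim(tok, cfg):
                if group:
                    items.append(ListItem(tuple(group)))
                    group = []
                delims.append(tok.text)
            elif tok.text.lower() in cfg.list_introducers:
                stopped = True
            else:
                group.insert(0, tok)
            i -= 1
        if group and len(items) < cfg.max_items:
            items.append(ListItem(tuple(group)))
        if items:
            candidates.append(
                CandidateList(
                    anchor=entity,
                    anchor_tokens=anchor_tokens,
                    items=tuple(reversed(items)),  # left-to-right order
                    delimiters=tuple(reversed(delims)),
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# substitution matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    matched_term: str
    split_index: int  # anchor tokens replaced by the item
    concept: tuple[str, str]  # (concept id, entity type)
    item_tokens: tuple[Token, ...]  # the fragment that matched (may be a suffix)


def substitute_and_match(
    item_tokens: Sequence[Token] | Sequence[str],
    anchor_tokens: Sequence[Token] | Sequence[str],
    lexicon: Lexicon,
    cfg: MinerConfig = MinerConfig(),
) -> list[MatchResult]:
    """Try substituting a list item for a prefix of the anchor term.

    For every split index ``j`` in ``1..len(anchor)-1`` the phrase
    ``item + anchor[j:]`` is normalized and looked up; the full item group
    is tried first, then trailing suffixes of it (leading words such as
    "Both" or "human" in "human breast and colorectal cancer" are not part
    of the member).  Hits are returned longest-replacement first: longer
    item fragments before shorter, larger ``j`` (more anchor words
    replaced) before smaller.  An empty result means no match.
    """
    def txt(tok) -> str:
        return tok.text if isinstance(tok, Token) else str(tok)

    items = list(item_tokens)
    anchors = [txt(t) for t in anchor_tokens]
    results: list[MatchResult] = []
    if not items or len(anchors) < 2:
        return results
    for drop in range(0, len(items)):
        frag = items[drop:]
        frag_words = [txt(t) for t in frag]
        for j in range(len(anchors) - 1, 0, -1):
            phrase = " ".join(frag_words + anchors[j:])
            for concept in sorted(lexicon.lookup(phrase)):
                results.append(
                    MatchResult(
                        matched_term=normalize_term(phrase),
                        split_index=j,
                        concept=concept,
                        item_tokens=tuple(
                            t for t in frag if isinstance(t, Token)
                        ) or tuple(),
                    )
                )
        if results:
            break  # longest fragment wins; do not try shorter suffixes
    return results


# ---------------------------------------------------------------------------
# document expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpandedMention:
    """A recovered elided list member as a multi-subspan entity."""

    doc_id: str
    section: str
    entity: Entity
    matched_term: str
    concept: tuple[str, str]
    split_index: int


def expand_document(
    doc: AnnotatedDocument,
    lexicon: Lexicon,
    cfg: MinerConfig = MinerConfig(),
) -> tuple[AnnotatedDocument, list[ExpandedMention]]:
    """Mine one document; return a copy with added multi-span entities.

    Original annotations are never modified.  For each candidate list the
    items are processed right-to-left (nearest the anchor first); a group
    with no match ends the scan when ``stop_on_unmatched`` is set, as does
    a group that only matched via a proper suffix (its leading words mark
    the left edge of the list).  An expansion that would cross an existing
    subspan is dropped.
    """
    lex = lexicon
    if lexicon.plural_folding != cfg.plural_folding:
        lex = Lexicon(entries=lexicon.entries, plural_folding=cfg.plural_folding)
    out = doc.copy()
    mentions: list[ExpandedMention] = []
    counter = 0
    for cand in detect_candidate_lists(doc, cfg):
        anchor_toks = cand.anchor_tokens
        if len(anchor_toks) < 2:
            continue
        for item in reversed(cand.items):  # nearest-to-anchor first
            hits = substitute_and_match(item.tokens, anchor_toks, lex, cfg)
            if not hits:
                if cfg.stop_on_unmatched:
                    break
                continue
            best = hits[0]
            tail = anchor_toks[best.split_index :]
            tail_span = Span(tail[0].begin, tail[-1].end)
            frag_toks = best.item_tokens
            frag_span = Span(frag_toks[0].begin, frag_toks[-1].end)
            subspans = normalize_subspans([frag_span, tail_span])
            crossing = any(
                spans_cross(ns, s)
                for ns in subspans
                for _, s in out.all_subspans()
            )
            if not crossing:
                counter += 1
                entity = Entity(
                    f"N{counter}" if not doc.source_id else f"N{doc.source_id}-{counter}",
                    best.concept[1],
                    subspans,
                )
                out.entities.append(entity)
                mentions.append(
                    ExpandedMention(
                        doc_id=doc.source_id or "",
                        section=doc.section_of(frag_span.begin),
                        entity=entity,
                        matched_term=best.matched_term,
                        concept=best.concept,
                        split_index=best.split_index,
                    )
                )
            if len(frag_toks) < len(item.tokens):
                break  # matched a proper suffix: list starts here
    return out, mentions


def expand_corpus(
    docs: Iterable[AnnotatedDocument],
    lexicon: Lexicon,
    cfg: MinerConfig = MinerConfig(),
) -> tuple[list[AnnotatedDocument], list[ExpandedMention]]:
    """Apply :func:`expand_document` over a corpus."""
    out_docs: list[AnnotatedDocument] = []
    all_mentions: list[ExpandedMention] = []
    for doc in docs:
        new_doc, mentions = expand_document(doc, lexicon, cfg)
        out_docs.append(new_doc)
        all_mentions.extend(mentions)
    return out_docs, all_mentions


def summarize_counts(mentions: Sequence[ExpandedMention]) -> pd.DataFrame:
    """Mention counts grouped by document section and by entity type.

    Returns a tidy frame with columns ``group`` ("section" or
    "entity_type"), ``key`` and ``count`` — the desk-scale analogue of a
    corpus overview figure.  Empty input yields an empty frame.
    """
    rows = []
    if mentions:
        sec = pd.Series([m.section for m in mentions]).value_counts()
        typ = pd.Series([m.concept[1] for m in mentions]).value_counts()
        for key, count in sec.items():
            rows.append({"group": "section", "key": key, "count": int(count)})
        for key, count in typ.items():
            rows.append({"group": "entity_type", "key": key, "count": int(count)})
    return pd.DataFrame(rows, columns=["group", "key", "count"])


def mentions_to_tsv(mentions: Sequence[ExpandedMention]) -> str:
    """TSV mention report: doc id, section, type, concept, matched term,
    and the subspan offsets as ``begin-end`` pairs joined by commas."""
    lines = ["doc_id\tsection\tentity_type\tconcept_id\tmatched_term\tsubspans"]
    for m in mentions:
        spans = ",".join(f"{s.begin}-{s.end}" for s in m.entity.subspans)
        lines.append(
            f"{m.doc_id}\t{m.section}\t{m.concept[1]}\t{m.concept[0]}\t"
            f"{m.matched_term}\t{spans}"
        )
    return "\n".join(lines) + "\n"
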