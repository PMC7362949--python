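"""Synthetic corpora with controlled coordination-list structure.

The generator emulates the situation the miner targets: abstracts that
contain list sentences such as

    "Patients developed renal-alpha1, gastric-beta2 and hepatic-gamma3
    carcinoma."

where only the final member ("hepatic-gamma3 carcinoma") is tagged — the
behaviour of large-scale taggers on elided lists — while the earlier
members exist only as modifier fragments sharing the head word.  Ground
truth records *all* intended members, so miner precision and recall can
be measured exactly at known lexicon coverage.

Controls: number of documents and lists, list-length distribution,
comma- vs slash-delimited lists, lexicon coverage ``p`` (each elided
member's term enters the emitted lexicon independently with probability
``p``), and a distractor rate (sentences joining unrelated words with
"and", paired with spurious lexicon entries, which create realistic
false-positive pressure).  Member modifiers are unique across a corpus,
so on clean templates recall is exactly binomial in ``p``.

A fixed seed gives byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .expansion import ExpandedMention, Lexicon
from .io import serialize_pubannotation
from .model import AnnotatedDocument, Entity, Span

__all__ = [
    "GeneratorConfig",
    "TruthEntity",
    "GroundTruth",
    "SyntheticCorpus",
    "generate_corpus",
    "EvaluationResult",
    "evaluate",
]

_MOD_BASES = [
    "renal", "hepatic", "gastric", "ovarian", "cervical", "prostatic",
    "dermal", "cardiac", "neural", "pulmonary", "colonic", "splenic",
    "adrenal", "thyroid", "pineal", "uterine", "retinal", "corneal",
    "tracheal", "bronchial",
]
_MOD_SUFFIXES = [
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "sigma", "omega", "rho", "tau", "phi",
]
_HEADS = {
    "Disease": ["carcinoma", "sarcoma", "lymphoma"],
    "Chemical": ["inhibitor", "antagonist"],
}
_PREFIXES = [
    "Patients developed",
    "Prior studies reported",
    "The cohort exhibited",
    "Clinicians frequently observed",
]
_SUFFIXES_TXT = ["", " in this cohort", " after treatment"]
_FILLERS = [
    "No additional findings were recorded.",
    "Samples were processed under a standard protocol.",
    "Follow-up visits were scheduled quarterly.",
]
_TITLE = "Synthetic abstract with elided coordination lists."


class ConfigError(ValueError):
    """The generator configuration is unusable."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    ``lists_per_doc`` and ``list_length`` are inclusive integer ranges
    sampled uniformly; ``coverage`` is the probability that an elided
    member's term appears in the emitted lexicon; ``distractor_rate`` is
    the expected number of distractor sentences per document;
    ``slash_fraction`` is the share of lists rendered with slashes
    instead of commas.
    """

    seed: int = 0
    n_docs: int = 100
    lists_per_doc: tuple[int, int] = (1, 2)
    list_length: tuple[int, int] = (2, 6)
    coverage: float = 1.0
    distractor_rate: float = 0.0
    slash_fraction: float = 0.2
    entity_types: tuple[str, ...] = ("Disease", "Chemical")

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ConfigError("coverage must lie in [0, 1]")
        if self.list_length[0] < 2:
            raise ConfigError("lists need at least 2 members")
        if self.n_docs < 1 or self.lists_per_doc[0] < 0:
            raise ConfigError("need at least one document")
        for t in self.entity_types:
            if t not in _HEADS or not _HEADS[t] or not _MOD_BASES:
                raise ConfigError(f"no heads/modifiers for entity type {t!r}")


@dataclass(frozen=True)
class TruthEntity:
    doc_id: str
    entity_type: str
    concept_id: str
    term: str
    subspans: tuple[Span, ...]
    elided: bool  # True for recovered-by-mining members, False for anchors


@dataclass
class GroundTruth:
    entities: list[TruthEntity] = field(default_factory=list)

    def doc_ids(self) -> set[str]:
        return {t.doc_id for t in self.entities}

    def elided(self) -> list[TruthEntity]:
        return [t for t in self.entities if t.elided]

    def to_tsv(self) -> str:
        lines = ["doc_id\tentity_type\tconcept_id\tterm\tsubspans\telided"]
        for t in self.entities:
            spans = ",".join(f"{s.begin}-{s.end}" for s in t.subspans)
            lines.append(
                f"{t.doc_id}\t{t.entity_type}\t{t.concept_id}\t{t.term}\t"
                f"{spans}\t{int(t.elided)}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class SyntheticCorpus:
    documents: list[AnnotatedDocument]
    truth: GroundTruth
    lexicon: Lexicon
    config: GeneratorConfig

    @property
    def pubtator(self) -> str:
        """The corpus rendered in PubTator pipe/tab form."""
        blocks = []
        for doc in self.documents:
            title, _, abstract = doc.text.partition("\n")
            lines = [f"{doc.source_id}|t|{title}", f"{doc.source_id}|a|{abstract}"]
            concepts = {a["subj"]: a["obj"] for a in doc.attributes}
            for e in doc.entities:
                s = e.subspans[0]
                mention = doc.text[s.begin : s.end]
                lines.append(
                    f"{doc.source_id}\t{s.begin}\t{s.end}\t{mention}\t{e.label}\t"
                    f"{concepts.get(e.id, '')}"
                )
            blocks.append("\n".join(lines))
        return "\n\n".join(blocks) + "\n"

    @property
    def pubannotation(self) -> list[dict]:
        """The corpus rendered as PubAnnotation JSON objects."""
        return [serialize_pubannotation(doc) for doc in self.documents]

    @property
    def lexicon_tsv(self) -> str:
        return self.lexicon.to_tsv()


class _ConceptRegistry:
    """Deterministic concept ids per (type, term), in first-seen order."""

    def __init__(self) -> None:
        self._ids: dict[tuple[str, str], str] = {}

    def id_for(self, entity_type: str, term: str) -> str:
        key = (entity_type, term)
        if key not in self._ids:
            prefix = entity_type[:1].upper()
            self._ids[key] = f"{prefix}{len(self._ids) + 1:05d}"
        return self._ids[key]


def generate_corpus(cfg: GeneratorConfig) -> SyntheticCorpus:
    """Generate documents, ground truth and a coverage-``p`` lexicon.

    Each list sentence tags only its final member; the lexicon contains
    every anchor term, each elided member term independently with
    probability ``coverage``, and (at the same rate) the spurious
    cross-type terms implied by distractor sentences.
    """
    rng = random.Random(cfg.seed)
    registry = _ConceptRegistry()
    lexicon = Lexicon()
    truth = GroundTruth()
    documents: list[AnnotatedDocument] = []

    mod_counter = 0

    def fresh_modifier() -> str:
        nonlocal mod_counter
        mod_counter += 1
        base = rng.choice(_MOD_BASES)
        suffix = rng.choice(_MOD_SUFFIXES)
        return f"{base}-{suffix}{mod_counter}"

    for d in range(cfg.n_docs):
        doc_id = str(100001 + d)
        sentences: list[tuple[str, list[dict]]] = []  # (text, records)

        n_lists = rng.randint(*cfg.lists_per_doc)
        for _ in range(n_lists):
            etype = rng.choice(cfg.entity_types)
            head = rng.choice(_HEADS[etype])
            k = rng.randint(*cfg.list_length)
            mods = [fresh_modifier() for _ in range(k)]
            use_slash = rng.random() < cfg.slash_fraction
            prefix = rng.choice(_PREFIXES) + " "
            suffix = rng.choice(_SUFFIXES_TXT) + "."

            if use_slash:
                body = "/".join(mods) + " " + head
            else:
                body = ", ".join(mods[:-1]) + " and " + mods[-1] + " " + head
            sentence = prefix + body + suffix

            # member offsets within the sentence
            records: list[dict] = []
            pos = len(prefix)
            head_begin = len(prefix) + len(body) - len(head)
            head_span = (head_begin, head_begin + len(head))
            for i, m in enumerate(mods):
                m_span = (pos, pos + len(m))
                term = f"{m} {head}"
                cid = registry.id_for(etype, term)
                last = i == k - 1
                records.append(
                    {
                        "type": etype,
                        "concept": cid,
                        "term": term,
                        "spans": [(m_span[0], head_span[0] + len(head))]
                        if last
                        else [m_span, head_span],
                        "elided": not last,
                    }
                )
                if last:
                    lexicon.add(cid, etype, term)
                elif rng.random() < cfg.coverage:
                    lexicon.add(cid, etype, term)
                if use_slash:
                    pos += len(m) + 1
                elif i < k - 2:
                    pos += len(m) + 2  # ", "
                else:
                    pos += len(m) + 5  # " and "
            sentences.append((sentence, records))

        n_distract = int(cfg.distractor_rate) + (
            1 if rng.random() < cfg.distractor_rate % 1 else 0
        )
        for _ in range(n_distract):
            etype = rng.choice(cfg.entity_types)
            other = rng.choice([t for t in cfg.entity_types if t != etype] or [etype])
            head = rng.choice(_HEADS[etype])
            w = fresh_modifier()
            anchor_mod = fresh_modifier()
            anchor_term = f"{anchor_mod} {head}"
            cid = registry.id_for(etype, anchor_term)
            lexicon.add(cid, etype, anchor_term)
            prefix = "Exposure to "
            sentence = f"{prefix}{w} and {anchor_term} was frequent."
            a_begin = len(prefix) + len(w) + len(" and ")
            records = [
                {
                    "type": etype,
                    "concept": cid,
                    "term": anchor_term,
                    "spans": [(a_begin, a_begin + len(anchor_term))],
                    "elided": False,
                }
            ]
            # lexicon noise: the spurious cross-type combination
            spurious = f"{w} {head}"
            if rng.random() < cfg.coverage:
                lexicon.add(registry.id_for(other, spurious), other, spurious)
            sentences.append((sentence, records))

        if rng.random() < 0.5:
            sentences.append((rng.choice(_FILLERS), []))
        rng.shuffle(sentences)

        # assemble abstract and shift offsets
        title = _TITLE
        abstract_parts: list[str] = []
        offset = len(title) + 1  # title + newline
        entities: list[Entity] = []
        attributes: list[dict] = []
        for sent, records in sentences:
            if abstract_parts:
                offset += 1  # joining space
            for rec in records:
                spans = tuple(Span(b + offset, e + offset) for b, e in rec["spans"])
                truth.entities.append(
                    TruthEntity(
                        doc_id=doc_id,
                        entity_type=rec["type"],
                        concept_id=rec["concept"],
                        term=rec["term"],
                        subspans=spans,
                        elided=rec["elided"],
                    )
                )
                if not rec["elided"]:
                    tid = f"T{len(entities) + 1}"
                    entities.append(Entity(tid, rec["type"], spans))
                    attributes.append(
                        {
                            "id": f"A{len(entities)}",
                            "subj": tid,
                            "pred": "concept",
                            "obj": rec["concept"],
                        }
                    )
            abstract_parts.append(sent)
            offset += len(sent)
        abstract = " ".join(abstract_parts)
        text = title + "\n" + abstract
        sections = {
            "title": Span(0, len(title)),
            "abstract": Span(len(title) + 1, len(text)),
        }
        documents.append(
            AnnotatedDocument(
                text=text,
                source_db="PubMed",
                source_id=doc_id,
                entities=entities,
                attributes=attributes,
                sections=sections,
            )
        )

    return SyntheticCorpus(
        documents=documents, truth=truth, lexicon=lexicon, config=cfg
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool  # False when there were no predictions


def evaluate(
    predicted: Sequence[ExpandedMention], truth: GroundTruth
) -> EvaluationResult:
    """Exact-offset, exact-type comparison of mined mentions against truth.

    Only elided (multi-span) truth members count — the miner never
    re-predicts the already-tagged anchors.  With no predictions,
    precision is reported as 0.0 with ``precision_defined=False``.
    """
    truth_ids = truth.doc_ids()
    truth_set = {
        (t.doc_id, t.entity_type, t.subspans) for t in truth.elided()
    }
    pred_set = set()
    for m in predicted:
        if m.doc_id not in truth_ids:
            raise KeyError(f"prediction for unknown document {m.doc_id!r}")
        pred_set.add((m.doc_id, m.entity.label, m.entity.subspans))
    tp = len(pred_set & truth_set)
    fp = len(pred_set - truth_set)
    fn = len(truth_set - pred_set)
    precision_defined = bool(pred_set)
    precision = tp / (tp + fp) if pred_set else 0.0
    recall = tp / (tp + fn) if truth_set else (1.0 if not pred_set else 0.0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EvaluationResult(tp, fp, fn, precision, recall, f1, precision_defined)
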