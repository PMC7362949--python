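"""Shared fixtures: embedded literature snippets and random valid documents."""

from __future__ import annotations

import random

import pytest

from noncontig import AnnotatedDocument, Entity, Lexicon, Relation, Span, spans_cross

# Real sentences (from public text-mining datasets) in which only the final
# list member carries a tag, used to exercise the coordination-list miner.
SNIPPETS = {
    "prostate": (
        "It is suggested that DLC1 is a candidate tumour suppressor gene for "
        "human liver cancer, as well as for prostate, lung, colorectal and "
        "breast cancers",
        "breast cancers",
        "Disease",
    ),
    "cheeses": (
        "Both French and German cheeses have previously been reported to "
        "contain M. psychrotolerans",
        "German cheeses",
        "Food",
    ),
    "breast": (
        "LARG at chromosome 11q23 has functional characteristics of a tumor "
        "suppressor in human breast and colorectal cancer",
        "colorectal cancer",
        "Disease",
    ),
    "skin": ("skin and lung cancer", "lung cancer", "Disease"),
    "methicillin": (
        "and used API tests to identify S. aureus and E-tests to determine "
        "methicillin/oxacillin resistance",
        "oxacillin resistance",
        "Phenotype",
    ),
}


def snippet_doc(name: str) -> AnnotatedDocument:
    text, anchor, label = SNIPPETS[name]
    i = text.index(anchor)
    return AnnotatedDocument(
        text=text,
        source_id=name,
        entities=[Entity("T1", label, (Span(i, i + len(anchor)),))],
    )


@pytest.fixture
def disease_lexicon() -> Lexicon:
    lex = Lexicon()
    rows = [
        ("MESH:D011471", "Disease", "prostate cancer"),
        ("MESH:D008175", "Disease", "lung cancer"),
        ("MESH:D015179", "Disease", "colorectal cancer"),
        ("MESH:D001943", "Disease", "breast cancer"),
        ("MESH:D012878", "Disease", "skin cancer"),
        ("FOOD:0001", "Food", "french cheese"),
        ("PHEN:0001", "Phenotype", "methicillin resistance"),
    ]
    for cid, etype, syn in rows:
        lex.add(cid, etype, syn)
    return lex


def random_valid_document(rng: random.Random, with_relations: bool = True) -> AnnotatedDocument:
    """A random document satisfying every structural invariant.

    Subspans are sampled rejecting any that would cross the laminar family
    built so far; entities get 1-3 subspans, so both contiguous and
    non-contiguous entities occur.
    """
    text_len = rng.randint(30, 150)
    text = "".join(rng.choice("abcdefgh ij") for _ in range(text_len))
    entities: list[Entity] = []
    placed: list[Span] = []
    for i in range(rng.randint(1, 7)):
        subs: list[Span] = []
        for _ in range(rng.randint(1, 3)):
            b = rng.randint(0, text_len - 2)
            e = rng.randint(b + 1, min(text_len, b + 12))
            s = Span(b, e)
            if all(not spans_cross(s, t) for t in placed + subs):
                subs.append(s)
        if not subs:
            continue
        ent = Entity(f"T{len(entities) + 1}", rng.choice(["Disease", "Gene", "Chemical"]), tuple(subs))
        if all(not spans_cross(s, t) for s in ent.subspans for t in placed):
            entities.append(ent)
            placed.extend(ent.subspans)
    relations: list[Relation] = []
    if with_relations and len(entities) >= 2:
        for j in range(rng.randint(0, 2)):
            a, b = rng.sample(entities, 2)
            relations.append(Relation(f"R{j + 1}", "associated_with", a.id, b.id))
    attributes = [
        {"id": f"A{k + 1}", "subj": rng.choice(entities).id, "pred": "negation", "obj": "true"}
        for k in range(rng.randint(0, 2))
        if entities
    ]
    return AnnotatedDocument(
        text=text,
        source_db="PubMed",
        source_id=str(rng.randint(1, 10**7)),
        entities=entities,
        relations=relations,
        attributes=attributes,
    )
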