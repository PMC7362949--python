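"""Build a document with a non-contiguous entity, validate it, and
round-trip it through PubAnnotation JSON in both span dialects.

The entity "skin cancer" is made of two fragments — "skin" and "cancer" —
in the phrase "skin and lung cancer"; validation enforces that no two
subspans partially overlap (they must nest or be disjoint).
"""

import json

from noncontig import (
    AnnotatedDocument, Entity, Span,
    covered_text, parse_pubannotation, serialize_pubannotation,
    validate_document,
)

doc = AnnotatedDocument(
    text="skin and lung cancer",
    entities=[
        Entity("T1", "Disease", (Span(0, 4), Span(14, 20))),   # skin ... cancer
        Entity("T2", "Disease", (Span(9, 20),)),               # lung cancer
    ],
)

print("violations:", validate_document(doc))           # [] -> valid
print("T1 reads as:", covered_text(doc, "T1"))         # fragments, space-joined

blob = serialize_pubannotation(doc)
print(json.dumps(blob, indent=2))
assert parse_pubannotation(blob).structurally_equal(doc)
print("parse(serialize(doc)) == doc: True")

# a crossing pair, by contrast, is flagged:
bad = AnnotatedDocument(
    text="breast cancer gene",
    entities=[
        Entity("T1", "Disease", (Span(0, 13),)),   # breast cancer
        Entity("T2", "Gene", (Span(7, 18),)),      # cancer gene -- crosses T1
    ],
)
for v in validate_document(bad):
    print("bad doc:", v.kind, "-", v.message)
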