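"""Convert between the legacy chaining representation and native
multi-subspan entities.

Older annotation data encodes a non-contiguous entity as several
contiguous entities: extra pieces typed "_FRAGMENT", tied to the labeled
piece by "_lexicallyChainedTo" relations.  chain_to_multispan collapses
each chain into one entity with a span list; multispan_to_chain re-emits
the legacy form, and the two are mutually inverse.
"""

from noncontig import (
    AnnotatedDocument, Entity, Relation, Span,
    chain_to_multispan, multispan_to_chain, covered_text,
)

legacy = AnnotatedDocument(
    text="skin and lung cancer",
    entities=[
        Entity("E1", "_FRAGMENT", (Span(0, 4),)),
        Entity("E2", "Disease", (Span(14, 20),)),
    ],
    relations=[Relation("R1", "_lexicallyChainedTo", "E1", "E2")],
)

native = chain_to_multispan(legacy)
(entity,) = native.entities
print("merged entity:", entity.id, entity.label,
      [(s.begin, s.end) for s in entity.subspans])
print("reads as:", covered_text(native, entity))
print("chain relations left:", len(native.relations))

back = multispan_to_chain(native)
print("re-chained:", [(e.id, e.label) for e in back.entities],
      "+", len(back.relations), "chain relation(s)")
assert chain_to_multispan(back).structurally_equal(native)
print("round trip is the identity: True")
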