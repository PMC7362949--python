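"""Mine elided list members from real literature snippets.

In "prostate, lung, colorectal and breast cancers" a tagger annotates
only "breast cancers".  The miner walks leftward from that anchor,
substitutes each earlier list member for the anchor's modifier, and
checks the phrase against a lexicon — recovering three non-contiguous
disease mentions that share the head word "cancers".
"""

from noncontig import (
    AnnotatedDocument, Entity, Lexicon, Span, covered_text, expand_document,
)

lexicon = Lexicon()
for cid, syn in [
    ("MESH:D011471", "prostate cancer"), ("MESH:D008175", "lung cancer"),
    ("MESH:D015179", "colorectal cancer"), ("MESH:D001943", "breast cancer"),
    ("MESH:D012878", "skin cancer"),
]:
    lexicon.add(cid, "Disease", syn)

text = ("It is suggested that DLC1 is a candidate tumour suppressor gene "
        "for human liver cancer, as well as for prostate, lung, colorectal "
        "and breast cancers")
i = text.index("breast cancers")
doc = AnnotatedDocument(
    text=text, source_id="19855840",
    entities=[Entity("T1", "Disease", (Span(i, i + len("breast cancers")),))],
)

out, mentions = expand_document(doc, lexicon)
print(f"recovered {len(mentions)} elided members:")
for m in mentions:
    spans = [(s.begin, s.end) for s in m.entity.subspans]
    print(f"  {covered_text(out, m.entity):22s} {m.concept[0]:14s} spans={spans}")
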