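"""Measure miner precision/recall on synthetic corpora with known truth.

The generator writes abstracts whose list sentences tag only the final
member, plus a lexicon containing each elided member's term with
probability p ("coverage").  On clean corpora the miner's recall equals
p up to binomial noise; distractor sentences plus spurious lexicon
entries pull precision below 1, mimicking the error profile of
dictionary matching on real text.
"""

from noncontig import (
    GeneratorConfig, MinerConfig, evaluate, expand_corpus, generate_corpus,
    parse_pubtator,
)

miner = MinerConfig(stop_on_unmatched=False)

print("coverage  distractors  recall   precision   (n elided)")
for p, distract in [(1.0, 0.0), (0.5, 0.0), (0.25, 0.0), (1.0, 1.0)]:
    corpus = generate_corpus(GeneratorConfig(
        seed=17, n_docs=300, lists_per_doc=(1, 1),
        coverage=p, distractor_rate=distract,
    ))
    docs = parse_pubtator(corpus.pubtator)
    _, mentions = expand_corpus(docs, corpus.lexicon, miner)
    r = evaluate(mentions, corpus.truth)
    print(f"  {p:4.2f}      {distract:4.2f}      {r.recall:6.4f}   {r.precision:6.4f}"
          f"      ({len(corpus.truth.elided())})")
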