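# Methods

## Span model and the laminar constraint

Offsets are 0-based, half-open, counted in Unicode code points — the
indexing PubAnnotation JSON uses — never bytes. Empty spans are
rejected; there is no use for a zero-width annotation. An entity's
subspans are canonicalized on construction: sorted by begin, with
overlapping *and adjacent* fragments merged. Merging adjacency gives a
unique canonical form, which is what makes round-trip comparisons and
undo/redo equality checks exact; two touching fragments carry no more
information than one.

Validation enforces a laminar family over the subspans of **all**
entities in a document, not merely within one entity: any two subspans
must be disjoint or nested. This mirrors the nesting structure that an
HTML-like markup of spans can express — partial overlap cannot be
rendered as nested tags — and it is also what keeps group selection and
innermost-entity resolution well defined. Violations (crossing pairs,
out-of-bounds spans, dangling relation endpoints, duplicate ids) are
collected and returned rather than raised, so a corpus validator can
summarize rather than stop at the first defect. The crossing check uses
a sweep over begin-sorted subspans; a brute-force all-pairs oracle backs
it in the tests. Relaxing the constraint for genuinely crossing
annotations is deliberately unexplored.

## Representation conversion

The legacy chaining encoding represents a non-contiguous entity as
several contiguous entities: extras typed `_FRAGMENT`, joined by
relations with predicate `_lexicallyChainedTo`. `chain_to_multispan`
takes connected components of the chain-relation graph (union-find),
requires exactly one non-fragment member per component (its label and id
survive), rejects cycles, and merges subspans by normalization. Chains
longer than two members are supported transitively. Attributes and
ordinary relations that referenced a collapsed fragment are re-pointed
to the merged entity so the conversion is lossless.

`multispan_to_chain` emits one entity per subspan, the **last** fragment
in text order keeping the original id and label — matching the
observation that in elided lists the final member is the fully written,
tagger-visible one — with `k-1` relations chaining consecutive pieces.
Which end of the relation the fragment occupies varies between corpora,
so it is configurable (`ChainConfig.direction`, default
fragment-as-subject); `chain_to_multispan` accepts the label on any
unique non-fragment member, so both conventions read back correctly.

## Edit semantics

Selections are plain character intervals; the semantics depend only on
where a highlight starts and ends relative to existing subspans, so no
UI machinery is modeled. Each operation validates its result before
committing: an edit either leaves the document laminar or is rejected
with no state change. Commands carry pre/post snapshots of the
annotation lists (entities are immutable records, so snapshots are
shallow and cheap), making undo exact to the element order. The
Add-subspan mode is session state, matching a toolbar toggle; toggling
costs a click but does not change the document and therefore does not
enter the undo history.

Directional rules: a selection starting inside a subspan and running
past its end extends that subspan rightward; the mirrored gesture —
ending inside the *first* subspan having started before it — extends
leftward. The mirror is our generalization: the rightward rule is the
canonical one and the interval alone cannot distinguish a leftward
extension from a shorten, so `extend_entity` and `shorten_entity` are
separate calls and a non-matching gesture raises a typed signal for the
caller to reinterpret. Shortening removes the intersection of the
selection with the entity: fully covered subspans are deleted, a
prefix-covered subspan is trimmed to its uncovered remainder, and
deleting the last subspan deletes the entity. A selection that would cut
a hole in the middle of one subspan necessarily starts inside the
entity and is thus rejected as ambiguous. Group selection at a position
returns all subspans of the entity whose containing subspan is
smallest — the innermost under nesting.

The cost model counts primitive interactions: entity creation from a
highlight 1 click, mode toggle 1, type assignment 2 (open the pallet,
pick), relation creation 2 (one per endpoint). Under these defaults the
canonical subspan script (`create, toggle, add_subspan, toggle`) costs
4 and the canonical chaining script (`create, create, set_label, toggle,
create_relation, set_label, toggle`) costs 10.

## Coordination-list mining

Tokenization is deliberately simple: maximal runs of letters, digits
and hyphens are words; `,` and `/` are delimiter tokens; offsets always
map back into the source text. Characters such as `.;:?!` and newlines
between tokens act as scan boundaries.

A candidate list is a contiguous tagged entity whose immediately
preceding token (whitespace apart) is the trigger word "and" or, when
slash lists are enabled, a directly attached `/`. Earlier members are
collected leftward as delimiter-separated token groups (delimiters:
comma, slash, interior "and"), stopping at a boundary, at a
quantifier-like list introducer ("both", "either", "neither",
"including"), or after `max_items` groups.

Matching substitutes a group for a leading prefix of the anchor term:
for each split index `j` from `len(anchor)-1` down to 1 the phrase
`group + anchor[j:]` is normalized (case-folded, whitespace-collapsed)
and looked up. The full group is tried first, then its trailing
suffixes, because the leftmost group of a list almost always absorbs
clause material that is not part of the member ("…suppressor in human
**breast** and colorectal cancer" scans as the group "human breast",
whose suffix "breast" is the member). The longest matching fragment
wins, and a match via a *proper* suffix ends the leftward scan: the
unmatched prefix marks where the list begins. Multi-token members such
as "non-small cell" still match as whole groups. Plural folding (on by
default) strips a terminal "s" during lookup only, so "prostate" +
"cancers" matches a lexicon "prostate cancer" while the emitted mention
keeps the plural surface form.

Each hit becomes a new entity whose subspans are the fragment plus the
shared anchor tail, labeled with the lexicon concept's type. Expansion
never touches pre-existing annotations, drops (and only drops) additions
that would violate the laminar constraint, and is deterministic.

`stop_on_unmatched` (default on) ends the scan at the first group with
no match, which bounds false positives on real prose where material to
the left of a list is unconstrained. On synthetic calibration corpora
it is turned off: there a coverage miss is an independent coin flip per
member, and stopping early would couple one member's recall to its
neighbours', turning a binomial quantity into a geometric one. The
recall-equals-coverage analyses therefore use
`MinerConfig(stop_on_unmatched=False)`.

## Synthetic corpora

The generator emulates exactly the structure the miner targets:
abstracts containing list sentences ("Patients developed X, Y and Z
carcinoma.", or slash-delimited variants) in which **only the final
member is tagged**, as large-scale taggers behave on elided lists.
Ground truth records every intended member — the final one as a
contiguous entity, earlier ones as two-fragment entities (modifier +
shared head).

Member modifiers are synthetic hyphenated tokens ("renal-alpha7")
unique across a corpus, so each elided member's term enters the emitted
lexicon as an independent Bernoulli(`coverage`) draw and recall on a
clean corpus is exactly binomial in `p`. Distractor sentences join an
unrelated word to a tagged entity with "and", and the corresponding
spurious cross-type term is added to the lexicon at the same rate,
creating the false positives that dominate dictionary matching on real
text; precision degrades measurably while recall is untouched. Defaults:
100 documents, 1–2 lists per document, list lengths 2–6, coverage 1.0,
no distractors, 20 % slash lists. Calibration runs use 500 single-list
documents (≈1 500 elided members), which keeps the full pipeline under
a second while making the 3-standard-deviation binomial band a few
percent wide.

What the generator does *not* emulate: natural vocabulary (its terms
are modifier+head compounds by construction), variable anchor lengths
beyond two tokens, nested or head-first lists ("CYPs 2B6, 2C8 and
2C19"), and anaphora. Passing recall/precision recovery therefore shows
the mining rule and its bookkeeping are correct, not that real-world
precision is high — on real literature, lexicon noise dominates, and
the head-first pattern is a documented miss of the leftward-scan rule.

Evaluation is exact-offset, exact-type set comparison against the
elided truth members. With zero predictions, precision is reported as
0.0 with an explicit `precision_defined=False` flag rather than NaN.

## Numerical and interface choices

- All randomness flows from one `random.Random(seed)`; a fixed seed
  yields byte-identical corpora, lexica and truth tables.
- JSON round-trip comparison is structural; key order is insignificant.
- Conversion and parsing errors are typed (`FormatError`,
  `ConversionError`, `LexiconError`) and name the offending denotation,
  line or chain.
- The CLI is a thin wrapper: exit 0 on success, 1 on data errors, 2 on
  usage errors; logs to stderr.

## Known limitations

- The miner only handles the tail-sharing pattern (members *before* a
  tagged anchor); head-first lists are not mined.
- Concept disambiguation is exact normalized lookup; a term mapping to
  several concepts yields the lexicographically first at expansion time.
- PubTator parsing expects well-formed title/abstract blocks; full-text
  section codes beyond `t`/`a` are not recognized.
- The edit model covers single-document sessions; there is no notion of
  concurrent editors.
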