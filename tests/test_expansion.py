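"""Coordination-list miner: lexicon, tokenizer, detection, substitution."""

import pytest
from hypothesis import given, settings, strategies as st

from noncontig import (
    AnnotatedDocument,
    Entity,
    MinerConfig,
    Span,
    covered_text,
    detect_candidate_lists,
    expand_document,
    load_lexicon,
    substitute_and_match,
    tokenize,
    summarize_counts,
    validate_document,
)
from noncontig.expansion import Lexicon, LexiconError, normalize_term

from conftest import SNIPPETS, snippet_doc


class TestLexicon:
    def test_load_and_normalized_lookup(self):
        lex = load_lexicon("D001943\tDisease\tbreast cancer\n")
        assert lex.lookup("Breast  Cancer") == {("D001943", "Disease")}

    def test_shared_synonym_unions_concepts(self):
        lex = load_lexicon("C1\tDisease\tgist\nC2\tGene\tGIST\n")
        assert lex.lookup("gist") == {("C1", "Disease"), ("C2", "Gene")}

    def test_empty_lexicon_matches_nothing(self):
        lex = load_lexicon("")
        assert len(lex) == 0 and lex.lookup("anything") == set()

    def test_malformed_row_names_line(self):
        with pytest.raises(LexiconError, match="line 2"):
            load_lexicon("C1\tDisease\tok\nbadrow-no-tabs\n")

    def test_plural_folding(self):
        lex = load_lexicon("C1\tDisease\tbreast cancer\n")
        assert lex.lookup("breast cancers") == {("C1", "Disease")}
        strict = load_lexicon("C1\tDisease\tbreast cancer\n", plural_folding=False)
        assert strict.lookup("breast cancers") == set()


class TestTokenize:
    def test_slash_list(self):
        toks = [t.text for t in tokenize("methicillin/oxacillin resistance")]
        assert toks == ["methicillin", "/", "oxacillin", "resistance"]

    def test_commas_and_hyphens(self):
        toks = [t.text for t in tokenize("prostate, non-small lung,")]
        assert toks == ["prostate", ",", "non-small", "lung", ","]

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="abc XY,-/.019", max_size=60))
    def test_offsets_reconstruct_source(self, text):
        for tok in tokenize(text):
            assert text[tok.begin : tok.end] == tok.text


class TestDetection:
    def test_list_items_scanned_leftward(self):
        doc = snippet_doc("prostate")
        (cand,) = detect_candidate_lists(doc)
        assert [t.text for t in cand.anchor_tokens] == ["breast", "cancers"]
        item_texts = [" ".join(t.text for t in item.tokens) for item in cand.items]
        # commas split the near groups; the clause prefix is absorbed into
        # the group ending in "prostate"
        assert item_texts[-2:] == ["lung", "colorectal"]
        assert item_texts[-3].endswith("prostate")

    def test_introducer_bounds_the_list(self):
        (cand,) = detect_candidate_lists(snippet_doc("cheeses"))
        assert [[t.text for t in i.tokens] for i in cand.items] == [["French"]]

    def test_no_trigger_no_candidate(self):
        doc = AnnotatedDocument(
            text="We studied lung cancer in mice",
            entities=[Entity("T1", "Disease", (Span(11, 22),))],
        )
        assert detect_candidate_lists(doc) == []

    def test_sentence_boundary_stops_scan(self):
        text = "Cohort one. Smoking and lung cancer were studied"
        doc = AnnotatedDocument(
            text=text,
            entities=[Entity("T1", "Disease", (Span(24, 35),))],
        )
        (cand,) = detect_candidate_lists(doc)
        assert [[t.text for t in i.tokens] for i in cand.items] == [["Smoking"]]

    def test_slash_trigger(self):
        (cand,) = detect_candidate_lists(snippet_doc("methicillin"))
        assert cand.delimiters[-1] == "/"


class TestSubstitution:
    LEX = Lexicon()
    LEX.add("D1", "Disease", "prostate cancer")
    LEX.add("D2", "Disease", "breast cancer")

    def test_plural_fold_match(self):
        hits = substitute_and_match(["prostate"], ["breast", "cancers"], self.LEX)
        assert [(h.matched_term, h.split_index) for h in hits] == [("prostate cancers", 1)]
        assert hits[0].concept == ("D1", "Disease")

    def test_item_substitutes_anchor_prefix(self):
        hits = substitute_and_match(["breast"], ["colorectal", "cancer"], self.LEX)
        assert hits[0].concept == ("D2", "Disease")

    def test_negative_control(self):
        assert substitute_and_match(["apples"], ["lung", "cancer"], self.LEX) == []

    def test_single_token_anchor_yields_nothing(self):
        assert substitute_and_match(["prostate"], ["cancers"], self.LEX) == []


EXPECTED_EXPANSIONS = {
    # snippet -> list of (covered text, normalized matched term)
    "prostate": ["colorectal cancers", "lung cancers", "prostate cancers"],
    "cheeses": ["French cheeses"],
    "breast": ["breast cancer"],
    "skin": ["skin cancer"],
    "methicillin": ["methicillin resistance"],
}


class TestExpandDocument:
    @pytest.mark.parametrize("name", sorted(EXPECTED_EXPANSIONS))
    def test_snippet_expansions(self, name, disease_lexicon):
        doc = snippet_doc(name)
        out, mentions = expand_document(doc, disease_lexicon)
        got = [covered_text(out, m.entity) for m in mentions]
        assert got == EXPECTED_EXPANSIONS[name]
        for m in mentions:  # offsets are exact: surface form == matched term
            assert normalize_term(covered_text(out, m.entity)) == m.matched_term

    def test_mentions_cover_matched_terms(self, disease_lexicon):
        for name in EXPECTED_EXPANSIONS:
            out, mentions = expand_document(snippet_doc(name), disease_lexicon)
            for m in mentions:
                surface = normalize_term(covered_text(out, m.entity))
                assert disease_lexicon.lookup(surface) >= {m.concept}

    def test_originals_untouched_and_output_valid(self, disease_lexicon):
        doc = snippet_doc("prostate")
        before = list(doc.entities)
        out, mentions = expand_document(doc, disease_lexicon)
        assert doc.entities == before
        assert out.entities[: len(before)] == before
        assert len(out.entities) == len(before) + len(mentions)
        assert validate_document(out) == []

    def test_no_trigger_returns_unchanged(self, disease_lexicon):
        doc = AnnotatedDocument(
            text="We studied lung cancer in mice",
            entities=[Entity("T1", "Disease", (Span(11, 22),))],
        )
        out, mentions = expand_document(doc, disease_lexicon)
        assert mentions == [] and out.structurally_equal(doc)

    def test_deterministic(self, disease_lexicon):
        doc = snippet_doc("prostate")
        first = expand_document(doc, disease_lexicon)
        second = expand_document(doc, disease_lexicon)
        assert first[0].structurally_equal(second[0])
        assert first[1] == second[1]

    def test_stop_on_unmatched_bounds_scan(self):
        lex = Lexicon()
        lex.add("D1", "Disease", "colorectal cancers")
        doc = snippet_doc("prostate")
        _, stopped = expand_document(doc, lex, MinerConfig(stop_on_unmatched=True))
        assert [m.matched_term for m in stopped] == ["colorectal cancers"]
        _, kept = expand_document(doc, lex, MinerConfig(stop_on_unmatched=False))
        assert [m.matched_term for m in kept] == ["colorectal cancers"]


class TestSummarize:
    def test_counts_by_section_and_type(self, disease_lexicon):
        _, mentions = expand_document(snippet_doc("prostate"), disease_lexicon)
        table = summarize_counts(mentions)
        by_section = table[table["group"] == "section"].set_index("key")["count"]
        by_type = table[table["group"] == "entity_type"].set_index("key")["count"]
        assert by_section.to_dict() == {"body": 3}
        assert by_type.to_dict() == {"Disease": 3}

    def test_empty_input(self):
        assert summarize_counts([]).empty
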