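"""Edit semantics: subspan mode, extend/shorten, undo/redo, click costs."""

import copy
import random

import pytest

from noncontig import (
    AnnotatedDocument,
    CostModel,
    CS_CHAIN,
    CS_SUBSPAN,
    EditSession,
    Entity,
    Selection,
    Span,
    script_cost,
    validate_document,
)
from noncontig.editing import EditRejected, NoOpEdit, NotAnExtension
from noncontig.model import ValidationError


def session(text="skin and lung cancer", entities=()):
    return EditSession(AnnotatedDocument(text=text, entities=list(entities)))


class TestCreateEntity:
    def test_creates_single_subspan_entity(self):
        s = session()
        eid = s.create_entity(Selection(14, 20), "Disease")
        assert s.document.entity(eid) == Entity(eid, "Disease", (Span(14, 20),))
        assert s.total_cost == 1

    def test_crossing_selection_rejected_atomically(self):
        s = session(entities=[Entity("T1", "X", (Span(4, 9),))])
        before = copy.deepcopy(s.document)
        with pytest.raises(EditRejected):
            s.create_entity(Selection(2, 6), "Y")
        assert s.document.entities == before.entities
        assert s.total_cost == 0 and s.undo_stack == []


class TestAddSubspan:
    def test_requires_mode_toggle(self):
        s = session(entities=[Entity("T1", "Disease", (Span(14, 20),))])
        with pytest.raises(EditRejected):
            s.add_subspan("T1", Selection(0, 4))
        s.toggle_subspan_mode()
        updated = s.add_subspan("T1", Selection(0, 4))
        assert updated.subspans == (Span(0, 4), Span(14, 20))

    def test_adjacent_selection_merges(self):
        s = session(text="x" * 20, entities=[Entity("T1", "X", (Span(0, 4),))])
        s.toggle_subspan_mode()
        assert s.add_subspan("T1", Selection(4, 8)).subspans == (Span(0, 8),)

    def test_crossing_subspan_rejected(self):
        s = session(
            text="x" * 20,
            entities=[Entity("T1", "X", (Span(12, 16),)), Entity("T2", "Y", (Span(4, 9),))],
        )
        s.toggle_subspan_mode()
        with pytest.raises(EditRejected):
            s.add_subspan("T1", Selection(2, 6))
        assert s.document.entity("T1").subspans == (Span(12, 16),)


class TestExtendShorten:
    def test_extend_rightward(self):
        s = session(text="x" * 20, entities=[Entity("T1", "X", (Span(5, 10),))])
        assert s.extend_entity("T1", Selection(8, 15)).subspans == (Span(5, 15),)

    def test_extend_last_subspan_of_noncontiguous_entity(self):
        s = session(text="x" * 30, entities=[Entity("T1", "X", (Span(0, 4), Span(14, 20)))])
        assert s.extend_entity("T1", Selection(16, 25)).subspans == (Span(0, 4), Span(14, 25))

    def test_extend_leftward_mirror(self):
        s = session(text="x" * 20, entities=[Entity("T1", "X", (Span(5, 10),))])
        assert s.extend_entity("T1", Selection(2, 7)).subspans == (Span(2, 10),)

    def test_extension_crossing_neighbor_rejected(self):
        s = session(
            text="x" * 30,
            entities=[Entity("T1", "X", (Span(5, 10),)), Entity("T2", "Y", (Span(12, 18),))],
        )
        with pytest.raises(EditRejected):
            s.extend_entity("T1", Selection(8, 15))

    def test_not_an_extension_signals_caller(self):
        s = session(text="x" * 20, entities=[Entity("T1", "X", (Span(5, 10),))])
        with pytest.raises(NotAnExtension):
            s.extend_entity("T1", Selection(0, 3))

    def test_shorten_from_left(self):
        s = session(text="x" * 20, entities=[Entity("T1", "X", (Span(5, 15),))])
        assert s.shorten_entity("T1", Selection(0, 8)).subspans == (Span(8, 15),)

    def test_shorten_removes_fully_highlighted_subspan(self):
        s = session(text="x" * 30, entities=[Entity("T1", "X", (Span(0, 4), Span(14, 20)))])
        assert s.shorten_entity("T1", Selection(12, 20)).subspans == (Span(0, 4),)

    def test_shorten_to_nothing_deletes_entity(self):
        s = session(text="x" * 20, entities=[Entity("T1", "X", (Span(5, 10),))])
        assert s.shorten_entity("T1", Selection(3, 10)) is None
        assert not s.document.has_entity("T1")

    def test_shorten_outside_entity_is_noop(self):
        s = session(text="x" * 20, entities=[Entity("T1", "X", (Span(5, 10),))])
        with pytest.raises(NoOpEdit):
            s.shorten_entity("T1", Selection(12, 15))

    def test_shorten_then_extend_restores_entity(self):
        s = session(text="x" * 20, entities=[Entity("T1", "X", (Span(5, 15),))])
        s.shorten_entity("T1", Selection(2, 8))
        # complementary leftward extension restores the removed prefix
        assert s.extend_entity("T1", Selection(5, 9)).subspans == (Span(5, 15),)


class TestSelectEntity:
    def test_click_selects_all_subspans(self):
        s = session(entities=[Entity("T1", "Disease", (Span(0, 4), Span(14, 20)))])
        assert s.select_entity(2) == (Span(0, 4), Span(14, 20))

    def test_click_between_fragments_selects_nothing(self):
        s = session(entities=[Entity("T1", "Disease", (Span(0, 4), Span(14, 20)))])
        assert s.select_entity(7) == ()

    def test_innermost_entity_wins_on_nesting(self):
        s = session(
            text="breast cancer gene",
            entities=[
                Entity("T1", "Disease", (Span(0, 13),)),
                Entity("T2", "Disease", (Span(7, 13),)),
            ],
        )
        assert s.select_entity(9) == (Span(7, 13),)
        assert s.select_entity(2) == (Span(0, 13),)


class TestUndoRedo:
    def test_undo_restores_prior_state(self):
        s = session(entities=[Entity("T1", "Disease", (Span(14, 20),))])
        s.toggle_subspan_mode()
        s.add_subspan("T1", Selection(0, 4))
        assert s.undo()
        assert s.document.entity("T1").subspans == (Span(14, 20),)
        assert s.redo()
        assert s.document.entity("T1").subspans == (Span(0, 4), Span(14, 20))

    def test_empty_stacks_are_noops(self):
        s = session()
        assert not s.undo() and not s.redo()

    def test_fresh_edit_clears_redo(self):
        s = session()
        s.create_entity(Selection(0, 4), "A")
        s.undo()
        s.create_entity(Selection(9, 13), "B")
        assert s.redo_stack == [] and not s.redo()

    def test_random_edit_scripts_fully_reversible(self):
        """k random valid edits then k undos restore the initial document;
        k redos restore every intermediate snapshot (50 random scripts)."""
        rng = random.Random(99)
        for _ in range(50):
            s = session(text="x" * 60)
            s.subspan_mode = True
            snapshots = [copy.deepcopy(s.document.entities)]
            applied = 0
            for _ in range(rng.randint(1, 12)):
                try:
                    op = rng.choice(["create", "add", "extend", "shorten", "label", "delete"])
                    ids = [e.id for e in s.document.entities]
                    b = rng.randint(0, 58)
                    sel = Selection(b, rng.randint(b + 1, min(60, b + 8)))
                    if op == "create" or not ids:
                        s.create_entity(sel, rng.choice("ABC"))
                    elif op == "add":
                        s.add_subspan(rng.choice(ids), sel)
                    elif op == "extend":
                        s.extend_entity(rng.choice(ids), sel)
                    elif op == "shorten":
                        s.shorten_entity(rng.choice(ids), sel)
                    elif op == "label":
                        s.set_label(rng.choice(ids), rng.choice("XYZ"))
                    else:
                        s.delete_entity(rng.choice(ids))
                except (EditRejected, NoOpEdit, NotAnExtension):
                    continue
                applied += 1
                assert validate_document(s.document) == []
                snapshots.append(copy.deepcopy(s.document.entities))
            for i in range(applied, 0, -1):
                assert s.undo()
                assert s.document.entities == snapshots[i - 1]
            for i in range(1, applied + 1):
                assert s.redo()
                assert s.document.entities == snapshots[i]


class TestCostModel:
    def test_canonical_script_costs(self):
        # the subspan workflow needs 4 clicks; the chaining workflow 10
        assert script_cost(CS_SUBSPAN) == 4
        assert script_cost(CS_CHAIN) == 10

    def test_session_replay_matches_script_cost(self):
        s = session()
        eid = s.create_entity(Selection(14, 20), "Disease")
        s.toggle_subspan_mode()
        s.add_subspan(eid, Selection(0, 4))
        s.toggle_subspan_mode()
        assert s.total_cost == script_cost(CS_SUBSPAN) == 4

    def test_additive_over_concatenation(self):
        assert script_cost(CS_SUBSPAN + CS_CHAIN) == script_cost(CS_SUBSPAN) + script_cost(CS_CHAIN)

    def test_singleton_and_errors(self):
        assert script_cost(["create_entity"]) == 1
        with pytest.raises(ValidationError):
            script_cost([])
        with pytest.raises(KeyError):
            script_cost(["warp_drive"])
        with pytest.raises(ValidationError):
            CostModel(create_entity=0)
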