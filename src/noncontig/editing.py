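"""Reversible annotation-editing commands with undo/redo and a click-cost model.

This module reproduces, as a programmatic state machine, the editing
semantics of a subspan-aware annotation editor:

* creating an entity from a text selection;
* an **Add subspan** mode in which the next selections are appended as
  extra subspans of the current entity;
* extend/shorten shortcuts driven by where a selection starts and ends
  relative to the entity's subspans;
* group selection (clicking any subspan selects all subspans of the
  innermost entity);
* an undo/redo stack where every command carries its exact inverse.

Every edit is atomic: it either leaves the document valid under the
laminar constraint or is rejected with no state change.

The :class:`CostModel` counts primitive user interactions (mouse clicks).
Under the default model the subspan workflow for one non-contiguous
entity costs 4 clicks (create span, toggle mode on, add subspan, toggle
mode off) while the legacy chaining workflow costs 10 (two entity
creations, a fragment type assignment, a switch to relation mode, a
relation creation, a relation type assignment, and a switch back).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import (
    AnnotatedDocument,
    Entity,
    LookupError_,
    Relation,
    Span,
    ValidationError,
    normalize_subspans,
    spans_cross,
)

__all__ = [
    "Selection",
    "CostModel",
    "EditRejected",
    "NoOpEdit",
    "NotAnExtension",
    "EditCommand",
    "EditSession",
    "script_cost",
    "CS_SUBSPAN",
    "CS_CHAIN",
]


class EditRejected(ValueError):
    """The edit would break a structural constraint; nothing changed."""


class NoOpEdit(Exception):
    """The selection does not touch the target; nothing to do."""


class NotAnExtension(Exception):
    """Signals the caller that the selection is not an extend gesture
    (interpret it as shorten or create instead)."""


Selection = Span  # a user text highlight is just a character interval


@dataclass(frozen=True)
class CostModel:
    """Clicks per primitive action.

    Creating an entity from a highlighted span is one click; toggling a
    toolbar mode is one click; assigning a type from the pallet is two
    (open the pallet, pick the type); creating a relation is two (click
    each endpoint).
    """

    create_entity: int = 1
    add_subspan: int = 1
    toggle_mode: int = 1
    set_label: int = 2
    create_relation: int = 2
    extend: int = 1
    shorten: int = 1
    delete_entity: int = 1

    def __post_init__(self) -> None:
        for kind in self.__dataclass_fields__:
            if getattr(self, kind) <= 0:
                raise ValidationError(f"cost of {kind!r} must be a positive integer")

    def cost_of(self, kind: str) -> int:
        if kind not in self.__dataclass_fields__:
            raise KeyError(f"unknown action kind {kind!r}")
        return getattr(self, kind)


#: canonical interaction scripts for annotating ONE non-contiguous entity
CS_SUBSPAN: tuple[str, ...] = ("create_entity", "toggle_mode", "add_subspan", "toggle_mode")
CS_CHAIN: tuple[str, ...] = (
    "create_entity",
    "create_entity",
    "set_label",        # type the first entity as a fragment
    "toggle_mode",      # switch to relation mode
    "create_relation",
    "set_label",        # type the relation as a lexical chain
    "toggle_mode",      # back to term mode
)


def script_cost(script: Sequence[str], cost_model: CostModel = CostModel()) -> int:
    """Total interaction cost of a script of primitive action kinds.

    Additive over concatenation; raises ``KeyError`` on an unknown kind
    and :class:`ValidationError` on an empty script.
    """
    if not script:
        raise ValidationError("script must be non-empty")
    return sum(cost_model.cost_of(kind) for kind in script)


@dataclass
class EditCommand:
    """A reversible document edit.

    Commands carry exact pre/post snapshots of the annotation lists
    (entities and relations are immutable records, so the snapshots are
    cheap shallow copies).  Applying the inverse therefore restores the
    prior document state exactly, including list order.
    """

    kind: str
    payload: dict
    pre_entities: list[Entity]
    pre_relations: list[Relation]
    post_entities: list[Entity]
    post_relations: list[Relation]


class EditSession:
    """A document under edit: undo/redo stacks, mode flags, cumulative cost."""

    def __init__(
        self, document: AnnotatedDocument, cost_model: CostModel = CostModel()
    ) -> None:
        self.document = document
        self.cost_model = cost_model
        self.undo_stack: list[EditCommand] = []
        self.redo_stack: list[EditCommand] = []
        self.total_cost: int = 0
        self.subspan_mode: bool = False
        self._id_counter = 0

    # -- internals ------------------------------------------------------

    def _fresh_id(self, prefix: str = "T") -> str:
        existing = {e.id for e in self.document.entities} | {
            r.id for r in self.document.relations
        }
        while True:
            self._id_counter += 1
            candidate = f"{prefix}{self._id_counter}"
            if candidate not in existing:
                return candidate

    def _check_selection(self, sel: Selection) -> None:
        if sel.begin < 0 or sel.end > len(self.document.text):
            raise EditRejected(
                f"selection ({sel.begin}, {sel.end}) outside the text"
            )

    def _crossing_conflict(self, span: Span, ignore_entity: str | None = None) -> str | None:
        """Id of an entity whose subspan the given span would cross, if any."""
        for e, s in self.document.all_subspans():
            if e.id == ignore_entity:
                continue
            if spans_cross(span, s):
                return e.id
        return None

    def _entity_would_cross(self, entity: Entity) -> str | None:
        for s in entity.subspans:
            hit = self._crossing_conflict(s, ignore_entity=entity.id)
            if hit is not None:
                return hit
        return None

    def _with_replaced(self, entity_id: str, new: Entity) -> list[Entity]:
        return [new if e.id == entity_id else e for e in self.document.entities]

    def _commit(
        self,
        kind: str,
        payload: dict,
        new_entities: list[Entity] | None = None,
        new_relations: list[Relation] | None = None,
    ) -> None:
        """Record and apply an edit; charges the cost for ``kind``."""
        cmd = EditCommand(
            kind,
            payload,
            pre_entities=list(self.document.entities),
            pre_relations=list(self.document.relations),
            post_entities=(
                new_entities if new_entities is not None else list(self.document.entities)
            ),
            post_relations=(
                new_relations if new_relations is not None else list(self.document.relations)
            ),
        )
        self._run(cmd, forward=True)
        self.undo_stack.append(cmd)
        self.redo_stack.clear()
        self.total_cost += self.cost_model.cost_of(kind)

    def _run(self, cmd: EditCommand, forward: bool) -> None:
        doc = self.document
        if forward:
            doc.entities = list(cmd.post_entities)
            doc.relations = list(cmd.post_relations)
        else:
            doc.entities = list(cmd.pre_entities)
            doc.relations = list(cmd.pre_relations)

    # -- operations -----------------------------------------------------

    def create_entity(self, sel: Selection, label: str) -> str:
        """Annotate the selected span as a new single-subspan entity."""
        self._check_selection(sel)
        conflict = self._crossing_conflict(sel)
        if conflict is not None:
            raise EditRejected(
                f"selection ({sel.begin}, {sel.end}) crosses a subspan of "
                f"entity {conflict!r}"
            )
        eid = self._fresh_id()
        entity = Entity(eid, label, (sel,))
        self._commit(
            "create_entity",
            {"id": eid, "label": label, "sel": sel},
            new_entities=self.document.entities + [entity],
        )
        return eid

    def toggle_subspan_mode(self) -> bool:
        """Flip the Add-subspan toolbar toggle (costs one click)."""
        self.subspan_mode = not self.subspan_mode
        self.total_cost += self.cost_model.cost_of("toggle_mode")
        return self.subspan_mode

    def add_subspan(self, entity_id: str, sel: Selection) -> Entity:
        """Append the selection as a new subspan of an existing entity.

        Requires the Add-subspan mode to be on (mirroring the toolbar
        toggle); the selection must not cross any existing subspan.
        Adjacent or overlapping selections merge into the neighbour.
        """
        if not self.subspan_mode:
            raise EditRejected("Add-subspan mode is off")
        self._check_selection(sel)
        old = self.document.entity(entity_id)
        updated = Entity(old.id, old.label, old.subspans + (sel,))
        conflict = self._entity_would_cross(updated)
        if conflict is not None:
            raise EditRejected(
                f"selection ({sel.begin}, {sel.end}) crosses a subspan of "
                f"entity {conflict!r}"
            )
        self._commit(
            "add_subspan",
            {"entity": entity_id, "sel": sel},
            new_entities=self._with_replaced(entity_id, updated),
        )
        return updated

    def extend_entity(self, entity_id: str, sel: Selection) -> Entity:
        """Grow a boundary subspan outward from a selection.

        A selection starting inside a subspan and running past its end
        extends that subspan rightward to ``sel.end``; the mirror gesture
        (ending inside the first subspan, starting before it) extends the
        first subspan leftward.  A selection with neither shape raises
        :class:`NotAnExtension` so the caller can treat it as shorten or
        create.
        """
        self._check_selection(sel)
        old = self.document.entity(entity_id)
        new_subspans: list[Span] | None = None
        for i, s in enumerate(old.subspans):
            if s.contains_offset(sel.begin) and sel.end > s.end:
                new_subspans = list(old.subspans)
                new_subspans[i] = Span(s.begin, sel.end)
                break
        if new_subspans is None:
            first = old.subspans[0]
            if first.begin < sel.end <= first.end and sel.begin < first.begin:
                new_subspans = [Span(sel.begin, first.end)] + list(old.subspans[1:])
        if new_subspans is None:
            raise NotAnExtension(
                f"selection ({sel.begin}, {sel.end}) does not start inside "
                f"entity {entity_id!r} and extend beyond it"
            )
        updated = Entity(old.id, old.label, tuple(new_subspans))
        conflict = self._entity_would_cross(updated)
        if conflict is not None:
            raise EditRejected(
                f"extension would cross a subspan of entity {conflict!r}"
            )
        self._commit(
            "extend",
            {"entity": entity_id, "sel": sel},
            new_entities=self._with_replaced(entity_id, updated),
        )
        return updated

    def shorten_entity(self, entity_id: str, sel: Selection) -> Entity | None:
        """Remove the selected text from the entity's subspans.

        The selection must begin outside all of the entity's subspans and
        reach into (or across) them; covered subspans are removed and a
        partially covered one is trimmed to the uncovered remainder.
        Deleting the last subspan deletes the entity (returns ``None``).
        A selection missing the entity entirely raises :class:`NoOpEdit`.
        """
        self._check_selection(sel)
        old = self.document.entity(entity_id)
        if any(s.contains_offset(sel.begin) for s in old.subspans):
            raise NotAnExtension(
                "selection starts inside the entity; interpret as extend"
            )
        kept: list[Span] = []
        touched = False
        for s in old.subspans:
            if sel.contains(s):
                touched = True  # subspan fully highlighted: removed
            elif s.contains_offset(sel.end) and sel.begin <= s.begin and sel.end > s.begin:
                touched = True
                kept.append(Span(sel.end, s.end))
            else:
                kept.append(s)
        if not touched:
            raise NoOpEdit(
                f"selection ({sel.begin}, {sel.end}) does not touch entity {entity_id!r}"
            )
        if kept:
            updated: Entity | None = Entity(old.id, old.label, tuple(kept))
            new_entities = self._with_replaced(entity_id, updated)
        else:
            updated = None
            new_entities = [e for e in self.document.entities if e.id != entity_id]
        self._commit("shorten", {"entity": entity_id, "sel": sel}, new_entities=new_entities)
        return updated

    def set_label(self, entity_id: str, label: str) -> Entity:
        """Assign an entity type from the pallet (two clicks)."""
        old = self.document.entity(entity_id)
        updated = Entity(old.id, label, old.subspans)
        self._commit(
            "set_label",
            {"entity": entity_id, "label": label},
            new_entities=self._with_replaced(entity_id, updated),
        )
        return updated

    def create_relation(self, predicate: str, subject_id: str, object_id: str) -> str:
        """Link two entities (two clicks: one per endpoint)."""
        for eid in (subject_id, object_id):
            if not self.document.has_entity(eid):
                raise LookupError_(f"no entity with id {eid!r}")
        rid = self._fresh_id("R")
        rel = Relation(rid, predicate, subject_id, object_id)
        self._commit(
            "create_relation",
            {"id": rid},
            new_relations=self.document.relations + [rel],
        )
        return rid

    def delete_entity(self, entity_id: str) -> None:
        """Remove an entity (its relations must be removed first)."""
        old = self.document.entity(entity_id)
        if any(
            r.subject == entity_id or r.object == entity_id
            for r in self.document.relations
        ):
            raise EditRejected(
                f"entity {entity_id!r} participates in relations; delete those first"
            )
        self._commit(
            "delete_entity",
            {"entity": entity_id},
            new_entities=[e for e in self.document.entities if e.id != entity_id],
        )

    def select_entity(self, position: int) -> tuple[Span, ...]:
        """All subspans of the innermost entity containing ``position``.

        Clicking any fragment of a non-contiguous entity highlights the
        whole entity.  With nested entities the innermost (smallest
        containing subspan) wins; outside every entity the selection is
        empty.
        """
        best: Entity | None = None
        best_len = None
        for e, s in self.document.all_subspans():
            if s.contains_offset(position):
                if best_len is None or len(s) < best_len:
                    best, best_len = e, len(s)
        return best.subspans if best is not None else ()

    # -- undo / redo ----------------------------------------------------

    def undo(self) -> bool:
        """Revert the most recent edit; False if there is nothing to undo."""
        if not self.undo_stack:
            return False
        cmd = self.undo_stack.pop()
        self._run(cmd, forward=False)
        self.redo_stack.append(cmd)
        return True

    def redo(self) -> bool:
        """Re-apply the most recently undone edit."""
        if not self.redo_stack:
            return False
        cmd = self.redo_stack.pop()
        self._run(cmd, forward=True)
        self.undo_stack.append(cmd)
        return True
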