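"""Flattening of nested single-argument regulatory events.

Extractors trained to follow the sentence closely produce chains like
``Positive-Regulation(C:Ang II, T:Positive-Regulation(T:MAPK))`` where the
inner regulation adds no information ("induces an increase in...").  The
rewrite system here removes such intermediary *single-argument* regulatory
events (a regulation-class event with a Theme but no Cause) wherever they
sit as the Theme of another regulation-class event, composing the two
polarities:

    ===========  ===========  =======
    outer        nested       result
    ===========  ===========  =======
    Pos          Pos          Pos
    Pos          Reg          Pos
    Reg          Pos          Pos
    Neg          Neg          Pos
    Reg          Reg          Reg
    Neg          Reg          Neg
    Neg          Pos          Neg
    Reg          Neg          Neg
    Pos          Neg          Neg
    ===========  ===========  =======

Some compositions change the polarity of the outer event (e.g. Reg over
Neg becomes Neg).  To avoid chaining inferences the text never licensed,
each root structure gets a budget of **one** polarity change: any later
composition that would change the type again instead forces the result to
unspecified regulation.  Rewriting proceeds outermost-first, re-scanning
from the root after every application, and always terminates (each step
removes one event).  The unmodified original structure is preserved
alongside the refined one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .model import (
    Document,
    EventOccurrence,
    EventTree,
    Gene,
    REGULATION_TYPES,
    ordered_args,
    to_tree,
)

_SHORT = {"positive_regulation": "Pos", "negative_regulation": "Neg", "regulation": "Reg"}
_LONG = {v: k for k, v in _SHORT.items()}

#: The nine polarity-composition rules, (outer, nested) -> result.
POLARITY_TABLE: dict[tuple[str, str], str] = {
    ("Pos", "Pos"): "Pos",
    ("Pos", "Reg"): "Pos",
    ("Reg", "Pos"): "Pos",
    ("Neg", "Neg"): "Pos",
    ("Reg", "Reg"): "Reg",
    ("Neg", "Reg"): "Neg",
    ("Neg", "Pos"): "Neg",
    ("Reg", "Neg"): "Neg",
    ("Pos", "Neg"): "Neg",
}


def compose_polarity(outer: str, nested: str) -> tuple[str, bool]:
    """Compose two regulation polarities per the rule table.

    Accepts either short (``Pos``/``Neg``/``Reg``) or internal event-type
    names and returns ``(result, is_type_change)`` in the same spelling as
    the input; ``is_type_change`` is true when the result differs from the
    outer type.
    """
    short_in = outer in _LONG
    o = outer if short_in else _SHORT.get(outer)
    n = nested if nested in _LONG else _SHORT.get(nested)
    if o not in _LONG or n not in _LONG:
        raise ValueError(f"compose_polarity needs regulation-class types, got {outer!r}, {nested!r}")
    result = POLARITY_TABLE[(o, n)]
    return (result if short_in else _LONG[result]), result != o


@dataclass
class RefinedEvent:
    """A refined event structure plus a link to its unmodified original."""

    structure: EventTree
    original: EventTree
    original_id: Optional[str]
    polarity_changes_used: int = 0
    forced_unspecified: bool = False
    #: (event_id, type) of each removed intermediary event, in removal order
    removed: list[tuple[Optional[str], str]] = field(default_factory=list)
    norm_score: Optional[float] = None


def _is_removable(child: Union[EventTree, Gene]) -> bool:
    return (
        isinstance(child, EventTree)
        and child.type in REGULATION_TYPES
        and not child.causes()
    )


def _find_redex(node: EventTree) -> Optional[tuple[EventTree, int]]:
    """First (outermost, Cause-before-Theme pre-order) rewritable position.

    Returns ``(parent, arg_index)`` where ``parent.args[arg_index]`` is a
    Theme that is a Cause-less regulation-class event under a
    regulation-class parent.
    """
    if node.type in REGULATION_TYPES:
        for i, (role, child) in enumerate(node.args):
            if role == "Theme" and _is_removable(child):
                return node, i
    for _, child in ordered_args(node):
        if isinstance(child, EventTree):
            found = _find_redex(child)
            if found is not None:
                return found
    return None


def refine(root: EventTree) -> RefinedEvent:
    """Apply the rewrite system to one event structure.

    The input tree is not modified; the result holds the refined copy, the
    original, the polarity-change bookkeeping, and the removed
    intermediaries for provenance.
    """
    original = root.copy()
    work = root.copy()
    changes_used = 0
    forced = False
    removed: list[tuple[Optional[str], str]] = []
    while True:
        redex = _find_redex(work)
        if redex is None:
            break
        parent, idx = redex
        nested = parent.args[idx][1]
        assert isinstance(nested, EventTree)
        result, is_change = compose_polarity(parent.type, nested.type)
        if is_change:
            if changes_used:
                result = "regulation"
                forced = True
            else:
                changes_used = 1
        removed.append((nested.event_id, nested.type))
        parent.type = result
        parent.args[idx] = ("Theme", nested.themes()[0])
    return RefinedEvent(
        structure=work,
        original=original,
        original_id=root.event_id,
        polarity_changes_used=changes_used,
        forced_unspecified=forced,
        removed=removed,
    )


def refine_document(doc: Document) -> list[RefinedEvent]:
    """Refine every root event of a document.

    The refined event inherits the normalized confidence of its original
    root occurrence (scores are attached before refinement; the classifier
    scored the extraction, not the rewrite).
    """
    out = []
    for e in doc.root_events():
        r = refine(to_tree(doc, e))
        r.norm_score = e.norm_score
        out.append(r)
    return out


def refine_corpus(docs: list[Document]) -> dict[str, list[RefinedEvent]]:
    """Refine all documents; returns ``doc_id -> refined root events``."""
    return {doc.doc_id: refine_document(doc) for doc in docs}


def refined_document(doc: Document, refined: list[RefinedEvent]) -> Document:
    """Re-materialize refined structures as a standoff document.

    Retained events keep their original trigger spans (the trigger word
    does not move even when polarity composition changed the event type);
    removed intermediaries simply have no counterpart.  Mentions and text
    are shared with the original document.
    """
    orig = doc.event_map()
    new = Document(doc_id=doc.doc_id, text=doc.text, mentions=list(doc.mentions))

    def add(node: Union[EventTree, Gene]) -> str:
        if isinstance(node, Gene):
            assert node.mention_id is not None
            return node.mention_id
        arg_ids = [(role, add(child)) for role, child in node.args]
        o = orig[node.event_id]
        eid = f"E{len(new.events) + 1}"
        new.events.append(
            EventOccurrence(
                eid, node.type, o.trigger_start, o.trigger_end, o.trigger_text, arg_ids
            )
        )
        return eid

    for r in refined:
        add(r.structure)
    return new
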