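"""Core domain types for event post-processing.

The event model follows the BioNLP'09 shared-task conventions: a document
carries gene/protein mentions (text-bound entities) and typed events whose
arguments are role-labelled (Theme/Cause) references to mentions or,
recursively, to other events.  Nine event types exist; five "physical"
single-argument types, binding, and the three regulation polarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

# Internal (lowercase snake_case) event type names.
SINGLE_THEME_TYPES = frozenset(
    {
        "gene_expression",
        "transcription",
        "localization",
        "protein_catabolism",
        "phosphorylation",
    }
)
REGULATION_TYPES = frozenset({"regulation", "positive_regulation", "negative_regulation"})
EVENT_TYPES = SINGLE_THEME_TYPES | {"binding"} | REGULATION_TYPES

#: Mapping internal type -> standoff (.a2) spelling.
ST_NAMES = {
    "gene_expression": "Gene_expression",
    "transcription": "Transcription",
    "localization": "Localization",
    "protein_catabolism": "Protein_catabolism",
    "phosphorylation": "Phosphorylation",
    "binding": "Binding",
    "regulation": "Regulation",
    "positive_regulation": "Positive_regulation",
    "negative_regulation": "Negative_regulation",
}
FROM_ST_NAMES = {v: k for k, v in ST_NAMES.items()}

ROLES = ("Cause", "Theme")


@dataclass
class GeneMention:
    """A gene/protein entity annotation bound to a text span.

    Offsets are 0-based, end-exclusive; ``surface`` must equal the text
    slice.  ``canonical`` is filled by the canonicalizer (lowercase
    alphanumeric, or "" when the surface has no alphanumeric content).
    ``family_keys`` maps a family-scheme name to a family id or "unmapped".
    """

    mention_id: str
    start: int
    end: int
    surface: str
    canonical: str = ""
    family_keys: dict[str, str] = field(default_factory=dict)


@dataclass
class EventOccurrence:
    """A typed event: trigger span plus role-labelled argument references.

    ``arguments`` is an ordered list of ``(role, target_id)`` where the
    target is a mention id or another event id in the same document.
    ``trigger_score`` / ``arg_scores`` hold raw SVM margins when a
    confidence sidecar is attached; ``norm_score`` is the aggregated
    normalized confidence (minimum of the z-scored components).
    """

    event_id: str
    type: str
    trigger_start: int
    trigger_end: int
    trigger_text: str
    arguments: list[tuple[str, str]] = field(default_factory=list)
    trigger_score: Optional[float] = None
    arg_scores: Optional[list[Optional[float]]] = None
    norm_score: Optional[float] = None

    def themes(self) -> list[str]:
        return [t for r, t in self.arguments if r == "Theme"]

    def causes(self) -> list[str]:
        return [t for r, t in self.arguments if r == "Cause"]


@dataclass
class Document:
    doc_id: str
    text: str
    mentions: list[GeneMention] = field(default_factory=list)
    events: list[EventOccurrence] = field(default_factory=list)

    def mention_map(self) -> dict[str, GeneMention]:
        return {m.mention_id: m for m in self.mentions}

    def event_map(self) -> dict[str, EventOccurrence]:
        return {e.event_id: e for e in self.events}

    def root_events(self) -> list[EventOccurrence]:
        """Events that are not an argument of any other event."""
        nested = {t for e in self.events for _, t in e.arguments if t.startswith("E")}
        return [e for e in self.events if e.event_id not in nested]


@dataclass(frozen=True)
class Gene:
    """A gene leaf in a resolved event tree.

    ``label`` is the display/bracket label; ``mention_id`` ties the leaf
    back to a document mention (None for trees parsed from bracket
    notation).
    """

    label: str
    mention_id: Optional[str] = None


@dataclass
class EventTree:
    """A fully resolved (reference-free) event structure.

    Bracket notation, signatures, refinement and pair extraction all
    operate on this form; ``Document`` events are converted via
    :func:`to_tree`.
    """

    type: str
    args: list[tuple[str, Union["EventTree", Gene]]] = field(default_factory=list)
    # provenance: event id of the occurrence this node came from, if any
    event_id: Optional[str] = None

    def themes(self) -> list[Union["EventTree", Gene]]:
        return [t for r, t in self.args if r == "Theme"]

    def causes(self) -> list[Union["EventTree", Gene]]:
        return [t for r, t in self.args if r == "Cause"]

    def genes(self) -> list[Gene]:
        """All gene leaves in pre-order (Cause before Theme at each level)."""
        out: list[Gene] = []
        for _, child in ordered_args(self):
            if isinstance(child, Gene):
                out.append(child)
            else:
                out.extend(child.genes())
        return out

    def iter_events(self) -> Iterator["EventTree"]:
        yield self
        for _, child in self.args:
            if isinstance(child, EventTree):
                yield from child.iter_events()

    def copy(self) -> "EventTree":
        return EventTree(
            self.type,
            [(r, c.copy() if isinstance(c, EventTree) else c) for r, c in self.args],
            self.event_id,
        )


def ordered_args(tree: EventTree) -> list[tuple[str, Union[EventTree, Gene]]]:
    """Arguments with Cause slots before Theme slots, original order otherwise."""
    return [(r, c) for r, c in tree.args if r == "Cause"] + [
        (r, c) for r, c in tree.args if r != "Cause"
    ]


def to_tree(doc: Document, event: EventOccurrence) -> EventTree:
    """Resolve a document event's id references into an :class:`EventTree`.

    Gene leaves are labelled with the mention surface.
    """
    mentions = doc.mention_map()
    events = doc.event_map()

    def build(eid: str) -> EventTree:
        e = events[eid]
        args: list[tuple[str, Union[EventTree, Gene]]] = []
        for role, target in e.arguments:
            if target in mentions:
                m = mentions[target]
                args.append((role, Gene(m.surface, m.mention_id)))
            else:
                args.append((role, build(target)))
        return EventTree(e.type, args, event_id=e.event_id)

    return build(event.event_id)


def tree_equal(a: Union[EventTree, Gene], b: Union[EventTree, Gene]) -> bool:
    """Structural equality by type, roles and gene labels (ids ignored)."""
    if isinstance(a, Gene) or isinstance(b, Gene):
        return isinstance(a, Gene) and isinstance(b, Gene) and a.label == b.label
    if a.type != b.type or len(a.args) != len(b.args):
        return False
    return all(ra == rb and tree_equal(ca, cb) for (ra, ca), (rb, cb) in zip(a.args, b.args))
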