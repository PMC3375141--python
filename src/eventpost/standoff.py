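"""Standoff annotation I/O and event-model validation.

A corpus is a directory of documents, each stored as up to four files
sharing a basename: ``<doc>.txt`` (text), ``<doc>.a1`` (gene/protein
entities), ``<doc>.a2`` (event triggers and events) and optionally
``<doc>.conf.tsv`` (raw classifier margins for triggers and arguments).

Entity lines are ``Tn<TAB>TYPE start end<TAB>surface``; the .a2 file mixes
trigger lines of the same shape with event lines
``En<TAB>EVENTTYPE:Tk Role:Target ...``.  Offsets are 0-based,
end-exclusive.  Event-type names are normalized to lowercase snake_case in
memory and written back in the standoff spelling (``Positive_regulation``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .model import (
    Document,
    EventOccurrence,
    FROM_ST_NAMES,
    GeneMention,
    REGULATION_TYPES,
    ROLES,
    SINGLE_THEME_TYPES,
    ST_NAMES,
)


class StandoffError(Exception):
    """Base class for standoff I/O failures."""


class ParseError(StandoffError):
    """A line does not match the standoff grammar."""


class IntegrityError(StandoffError):
    """An annotation references an id that does not exist (or twice)."""


class ValidationError(StandoffError):
    """The document violates the event-model argument constraints."""


@dataclass(frozen=True)
class Violation:
    event_id: str
    rule: str
    message: str


_ENTITY_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_EVENT_RE = re.compile(r"^(E\d+)\t(\S+):(T\d+)((?: \S+:\S+)*)\s*$")


def _norm_type(name: str, line_no: int, stream: str) -> str:
    if name in FROM_ST_NAMES:
        return FROM_ST_NAMES[name]
    low = name.lower().replace("-", "_")
    if low in ST_NAMES:
        return low
    raise ParseError(f"{stream} line {line_no}: unknown event type {name!r}")


def read_standoff(
    entity_stream: str,
    event_stream: str,
    doc_text: str,
    doc_id: str = "doc",
    validate: bool = True,
) -> Document:
    """Parse entity and event streams against a document text.

    Raises :class:`ParseError` for malformed lines, :class:`IntegrityError`
    for dangling references, and :class:`ValidationError` when the event
    model's argument constraints are violated (unless ``validate=False``).
    """
    doc = Document(doc_id=doc_id, text=doc_text)
    triggers: dict[str, tuple[str, int, int, str]] = {}

    for line_no, line in enumerate(entity_stream.splitlines(), start=1):
        if not line.strip():
            continue
        m = _ENTITY_RE.match(line)
        if m is None:
            raise ParseError(f"entity stream line {line_no}: malformed line {line!r}")
        tid, _etype, start, end, surface = m.groups()
        doc.mentions.append(GeneMention(tid, int(start), int(end), surface))

    mention_ids = {m.mention_id for m in doc.mentions}
    for line_no, line in enumerate(event_stream.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _ENTITY_RE.match(line)
            if m is None:
                raise ParseError(f"event stream line {line_no}: malformed trigger {line!r}")
            tid, etype, start, end, surface = m.groups()
            triggers[tid] = (_norm_type(etype, line_no, "event stream"), int(start), int(end), surface)
            continue
        m = _EVENT_RE.match(line)
        if m is None:
            raise ParseError(f"event stream line {line_no}: malformed event {line!r}")
        eid, etype, trig_id, rest = m.groups()
        etype = _norm_type(etype, line_no, "event stream")
        if trig_id not in triggers:
            raise IntegrityError(f"event {eid}: unknown trigger {trig_id}")
        args: list[tuple[str, str]] = []
        for piece in rest.split():
            role, _, target = piece.partition(":")
            # accept numbered roles (Theme2, Theme3) from other writers
            base = role.rstrip("0123456789")
            if base not in ROLES:
                raise ParseError(f"event stream line {line_no}: unknown role {role!r}")
            args.append((base, target))
        ttype, tstart, tend, ttext = triggers[trig_id]
        if ttype != etype:
            raise ParseError(f"event {eid}: trigger type {ttype!r} differs from event type {etype!r}")
        doc.events.append(EventOccurrence(eid, etype, tstart, tend, ttext, args))

    known = mention_ids | {e.event_id for e in doc.events}
    for e in doc.events:
        for _, target in e.arguments:
            if target not in known:
                raise IntegrityError(f"event {e.event_id}: dangling reference {target}")

    if validate:
        violations = validate_event_constraints(doc)
        if violations:
            v = violations[0]
            raise ValidationError(
                f"{doc_id}: {len(violations)} constraint violation(s); "
                f"first: event {v.event_id} breaks rule {v.rule} ({v.message})"
            )
    return doc


def validate_event_constraints(doc: Document) -> list[Violation]:
    """Check the argument constraints of the nine-type event model.

    Violations are returned as data (empty list means valid): single-theme
    physical types take exactly one mention Theme; binding takes one or
    more mention Themes and no Cause; regulation-class events take exactly
    one Theme and at most one Cause, each a mention or event; the argument
    graph must be acyclic and all offsets must match the text.
    """
    out: list[Violation] = []
    mentions = doc.mention_map()
    events = doc.event_map()

    for m in doc.mentions:
        if not (0 <= m.start < m.end <= len(doc.text)):
            out.append(Violation(m.mention_id, "offset-bounds", f"span {m.start}..{m.end} outside text"))
        elif doc.text[m.start : m.end] != m.surface:
            out.append(
                Violation(m.mention_id, "offset-surface", f"surface {m.surface!r} != text slice")
            )

    for e in doc.events:
        if 0 <= e.trigger_start < e.trigger_end <= len(doc.text):
            if doc.text[e.trigger_start : e.trigger_end] != e.trigger_text:
                out.append(Violation(e.event_id, "offset-surface", "trigger text != text slice"))
        else:
            out.append(Violation(e.event_id, "offset-bounds", "trigger span outside text"))

        roles = [r for r, _ in e.arguments]
        targets = [t for _, t in e.arguments]
        unresolved = [t for t in targets if t not in mentions and t not in events]
        if unresolved:
            out.append(Violation(e.event_id, "dangling-reference", f"unknown target(s) {unresolved}"))
            continue
        if e.type in SINGLE_THEME_TYPES:
            if roles != ["Theme"] or targets[0] not in mentions:
                out.append(
                    Violation(
                        e.event_id,
                        "single-theme-type",
                        f"{e.type} must have exactly one mention Theme, got {e.arguments}",
                    )
                )
        elif e.type == "binding":
            if "Cause" in roles:
                out.append(Violation(e.event_id, "binding-no-cause", "binding cannot have a Cause"))
            if not roles or any(r != "Theme" for r in roles if r != "Cause") or not all(
                t in mentions for r, t in e.arguments if r == "Theme"
            ) or "Theme" not in roles:
                out.append(
                    Violation(
                        e.event_id,
                        "binding-theme",
                        "binding needs >=1 Theme arguments, all gene/protein mentions",
                    )
                )
        elif e.type in REGULATION_TYPES:
            if roles.count("Theme") != 1 or roles.count("Cause") > 1 or len(roles) != len(
                [r for r in roles if r in ROLES]
            ):
                out.append(
                    Violation(
                        e.event_id,
                        "regulation-args",
                        "regulation needs exactly one Theme and at most one Cause",
                    )
                )
        else:  # pragma: no cover - parser already restricts types
            out.append(Violation(e.event_id, "unknown-type", e.type))

    # cycle check over event->event references
    color: dict[str, int] = {}

    def visit(eid: str) -> bool:
        color[eid] = 1
        for _, t in events[eid].arguments:
            if t in events:
                c = color.get(t, 0)
                if c == 1 or (c == 0 and visit(t)):
                    return True
        color[eid] = 2
        return False

    for e in doc.events:
        if color.get(e.event_id, 0) == 0 and visit(e.event_id):
            out.append(Violation(e.event_id, "cycle", "event argument graph is cyclic"))
    return out


def write_standoff(doc: Document) -> tuple[str, str]:
    """Serialize a document back to ``(entity_stream, event_stream)``.

    Annotation ids are renumbered (entities first, then triggers continue
    the T namespace); ``read_standoff`` on the output reproduces the
    document up to this renaming.
    """
    a1, a2, _ = _write_standoff_mapped(doc)
    return a1, a2


def _write_standoff_mapped(doc: Document) -> tuple[str, str, dict[str, str]]:
    ent_lines = []
    id_map: dict[str, str] = {}
    for i, m in enumerate(doc.mentions, start=1):
        tid = f"T{i}"
        id_map[m.mention_id] = tid
        ent_lines.append(f"{tid}\t{'Protein'} {m.start} {m.end}\t{m.surface}")

    ev_lines = []
    next_t = len(doc.mentions) + 1
    for j, e in enumerate(doc.events, start=1):
        id_map[e.event_id] = f"E{j}"
    for e in doc.events:
        tid = f"T{next_t}"
        next_t += 1
        name = ST_NAMES[e.type]
        ev_lines.append(f"{tid}\t{name} {e.trigger_start} {e.trigger_end}\t{e.trigger_text}")
        args = " ".join(f"{role}:{id_map[t]}" for role, t in e.arguments)
        ev_lines.append(f"{id_map[e.event_id]}\t{name}:{tid}" + (f" {args}" if args else ""))
    return (
        "\n".join(ent_lines) + ("\n" if ent_lines else ""),
        "\n".join(ev_lines) + ("\n" if ev_lines else ""),
        id_map,
    )


def read_confidence_sidecar(stream: str, doc: Document) -> Document:
    """Attach raw classifier margins from a TSV sidecar to a document.

    Rows are ``doc_id<TAB>ref<TAB>kind<TAB>score`` with ``ref`` either
    ``<event_id>#trigger`` or ``<event_id>#<arg_index>``.  Duplicate refs
    are an integrity error (they indicate an upstream pipeline bug rather
    than a legitimate re-score).
    """
    events = doc.event_map()
    seen: set[str] = set()
    for line_no, line in enumerate(stream.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ParseError(f"sidecar line {line_no}: expected 4 TSV fields, got {len(parts)}")
        row_doc, ref, kind, score_s = parts
        if row_doc != doc.doc_id:
            raise IntegrityError(f"sidecar line {line_no}: doc id {row_doc!r} != {doc.doc_id!r}")
        try:
            score = float(score_s)
        except ValueError:
            raise ParseError(f"sidecar line {line_no}: non-numeric score {score_s!r}") from None
        if ref in seen:
            raise IntegrityError(f"sidecar line {line_no}: duplicate row for {ref}")
        seen.add(ref)
        eid, _, slot = ref.partition("#")
        if eid not in events:
            raise IntegrityError(f"sidecar line {line_no}: unknown event {eid}")
        e = events[eid]
        if kind == "trigger" and slot == "trigger":
            e.trigger_score = score
        elif kind == "argument" and slot.isdigit():
            idx = int(slot)
            if idx >= len(e.arguments):
                raise IntegrityError(f"sidecar line {line_no}: {eid} has no argument {idx}")
            if e.arg_scores is None:
                e.arg_scores = [None] * len(e.arguments)
            e.arg_scores[idx] = score
        else:
            raise ParseError(f"sidecar line {line_no}: bad kind/ref combination {kind!r}/{ref!r}")
    return doc


def write_confidence_sidecar(doc: Document, id_map: Optional[dict[str, str]] = None) -> str:
    lines = []
    rid = (lambda e: id_map.get(e, e)) if id_map else (lambda e: e)
    for e in doc.events:
        if e.trigger_score is not None:
            lines.append(f"{doc.doc_id}\t{rid(e.event_id)}#trigger\ttrigger\t{e.trigger_score!r}")
        if e.arg_scores is not None:
            for i, s in enumerate(e.arg_scores):
                if s is not None:
                    lines.append(f"{doc.doc_id}\t{rid(e.event_id)}#{i}\targument\t{s!r}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_document(txt_path: Path, validate: bool = True) -> Document:
    """Read one document from its ``.txt`` path (siblings ``.a1``/``.a2``/``.conf.tsv``)."""
    txt_path = Path(txt_path)
    base = txt_path.with_suffix("")
    text = txt_path.read_text(encoding="utf-8")
    a1 = base.with_suffix(".a1")
    a2 = base.with_suffix(".a2")
    doc = read_standoff(
        a1.read_text(encoding="utf-8") if a1.exists() else "",
        a2.read_text(encoding="utf-8") if a2.exists() else "",
        text,
        doc_id=base.name,
        validate=validate,
    )
    conf = Path(str(base) + ".conf.tsv")
    if conf.exists():
        read_confidence_sidecar(conf.read_text(encoding="utf-8"), doc)
    return doc


def read_corpus(directory: Path, validate: bool = True) -> list[Document]:
    """Read every document in a corpus directory, sorted by doc id."""
    directory = Path(directory)
    docs = [read_document(p, validate=validate) for p in sorted(directory.glob("*.txt"))]
    ids = [d.doc_id for d in docs]
    if len(set(ids)) != len(ids):  # pragma: no cover - glob gives unique basenames
        raise IntegrityError("duplicate doc ids in corpus")
    return docs


def write_corpus(docs: Iterable[Document], directory: Path, sidecars: bool = True) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        a1, a2, id_map = _write_standoff_mapped(doc)
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        (directory / f"{doc.doc_id}.a1").write_text(a1, encoding="utf-8")
        (directory / f"{doc.doc_id}.a2").write_text(a2, encoding="utf-8")
        if sidecars:
            conf = write_confidence_sidecar(doc, id_map)
            if conf:
                (directory / f"{doc.doc_id}.conf.tsv").write_text(conf, encoding="utf-8")
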