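"""Bracket notation and structural event signatures.

Events are written ``Type(Role:arg, ...)`` with ``C:``/``T:`` role markers,
e.g. ``Positive-Regulation(C:IL-2, T:Binding(T:NF-κB, T:p55))``.  A
*signature* abstracts such a structure into one of a small set of shape
patterns: any regulation polarity collapses to ``*Reg``, any single-Theme
physical type to ``Phy``, binding stays ``Bind``, and concrete genes become
placeholders ``A, B, ...`` assigned in traversal order (Cause slots before
Theme slots).  Counting signatures over a corpus yields the pattern
prevalence table used to characterise which structures dominate the data.
"""

from __future__ import annotations

from typing import Iterable, Union

import pandas as pd

from .model import EventTree, Gene, REGULATION_TYPES, SINGLE_THEME_TYPES, ordered_args

_DISPLAY = {
    "gene_expression": "Gene-Expression",
    "transcription": "Transcription",
    "localization": "Localization",
    "protein_catabolism": "Protein-Catabolism",
    "phosphorylation": "Phosphorylation",
    "binding": "Binding",
    "regulation": "Regulation",
    "positive_regulation": "Positive-Regulation",
    "negative_regulation": "Negative-Regulation",
}
_ALIASES = {name.lower(): t for t, name in _DISPLAY.items()}
_ALIASES.update(
    {
        "pos": "positive_regulation",
        "neg": "negative_regulation",
        "reg": "regulation",
        "bind": "binding",
        "phos": "phosphorylation",
        "expr": "gene_expression",
        "loc": "localization",
        "cat": "protein_catabolism",
        "tx": "transcription",
    }
)
_ROLE_ALIASES = {"c": "Cause", "cause": "Cause", "t": "Theme", "theme": "Theme"}


class BracketParseError(ValueError):
    """Malformed bracket notation; carries the character position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


def parse_bracket(s: str) -> EventTree:
    """Parse bracket notation into an :class:`EventTree`.

    Type names are case-insensitive and accept both the full hyphenated
    spellings and the short forms ``Pos``/``Neg``/``Reg``/``Bind``/``Phos``.
    """
    pos = 0
    n = len(s)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and s[pos] in " \t":
            pos += 1

    def parse_node() -> Union[EventTree, Gene]:
        nonlocal pos
        skip_ws()
        start = pos
        while pos < n and s[pos] not in "(),:":
            pos += 1
        token = s[start:pos].strip()
        if pos < n and s[pos] == "(":
            etype = _ALIASES.get(token.lower())
            if etype is None:
                raise BracketParseError(f"unknown event type {token!r}", start)
            pos += 1  # consume '('
            args: list[tuple[str, Union[EventTree, Gene]]] = []
            while True:
                skip_ws()
                if pos >= n:
                    raise BracketParseError("unbalanced parentheses", start)
                if s[pos] == ")":
                    pos += 1
                    break
                rstart = pos
                while pos < n and s[pos] not in ":(),":
                    pos += 1
                if pos >= n or s[pos] != ":":
                    raise BracketParseError("expected 'Role:' before argument", rstart)
                role = _ROLE_ALIASES.get(s[rstart:pos].strip().lower())
                if role is None:
                    raise BracketParseError(f"unknown role {s[rstart:pos].strip()!r}", rstart)
                pos += 1  # consume ':'
                args.append((role, parse_node()))
                skip_ws()
                if pos < n and s[pos] == ",":
                    pos += 1
            return EventTree(etype, args)
        if not token:
            raise BracketParseError("empty gene label", start)
        return Gene(token)

    node = parse_node()
    skip_ws()
    if pos != n:
        raise BracketParseError(f"trailing input {s[pos:]!r}", pos)
    if isinstance(node, Gene):
        raise BracketParseError("top-level expression must be an event", 0)
    return node


def print_bracket(node: Union[EventTree, Gene]) -> str:
    """Render a tree in canonical bracket notation (inverse of the parser)."""
    if isinstance(node, Gene):
        return node.label
    parts = [f"{'C' if role == 'Cause' else 'T'}:{print_bracket(child)}" for role, child in node.args]
    return f"{_DISPLAY[node.type]}({', '.join(parts)})"


def signature(tree: EventTree) -> str:
    """Structural signature of an event tree.

    Deterministic: isomorphic structures (up to trigger wording, ids and
    gene identity) share a signature.  Repeated genes still get distinct
    placeholders — gene identity inside a signature is positional only.
    """
    counter = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

    def walk(node: Union[EventTree, Gene]) -> str:
        if isinstance(node, Gene):
            return next(counter)
        if node.type in REGULATION_TYPES:
            head = "*Reg"
        elif node.type in SINGLE_THEME_TYPES:
            head = "Phy"
        else:
            head = "Bind"
        parts = [
            f"{'C' if role == 'Cause' else 'T'}:{walk(child)}"
            for role, child in ordered_args(node)
        ]
        return f"{head}({', '.join(parts)})"

    return walk(tree)


def count_signatures(trees: Iterable[EventTree]) -> pd.DataFrame:
    """Tabulate signature prevalence over root event structures.

    Returns a frame with columns ``signature, count, pct, cum_pct`` sorted
    by count (descending), ties broken by signature; percentages are over
    all supplied trees and sum to 100.
    """
    counts: dict[str, int] = {}
    total = 0
    for t in trees:
        counts[signature(t)] = counts.get(signature(t), 0) + 1
        total += 1
    if total == 0:
        return pd.DataFrame(columns=["signature", "count", "pct", "cum_pct"])
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["signature", "count"])
    df["pct"] = df["count"] / total * 100.0
    df["cum_pct"] = df["pct"].cumsum()
    return df


def write_signature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
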