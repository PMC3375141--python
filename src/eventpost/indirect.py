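"""Indirect (hypothesis-level) gene associations via shared partners.

Aggregated pairwise associations are joined through a common partner gene
Z to surface links no single sentence states:

* **coregulation** — A>Z and B>Z: A and B coregulate Z;
* **common_regulator** — Z>A and Z>B: A and B are regulated by Z;
* **common_binding_partner** — A×Z and B×Z: shared binding partner Z.

Regulation and indirect-regulation edges both participate in the
regulatory joins (an indirect regulation still asserts regulation);
coregulation_capture seeds — Cause pairs discarded during pairwise
abstraction — feed only the coregulation join, contributing their captured
target genes directly.  These links are hypotheses, not extracted claims:
coregulation in the biological sense additionally requires coexpression,
which text-mined events alone cannot establish, so every record carries a
``hypothetical`` flag.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .pairs import GenePair

ASSOCIATION_KINDS = ("coregulation", "common_regulator", "common_binding_partner")

_REGULATORY = {"regulation", "indirect_regulation"}


@dataclass
class IndirectAssociation:
    """Two genes linked through >=1 shared partner by one join pattern."""

    kind: str
    key_a: str
    key_b: str
    #: shared partner -> supporting edge scores (best per side kept)
    shared: dict[str, list[float]] = field(default_factory=dict)
    hypothetical: bool = True

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def best_score(self) -> float:
        scores = [s for ss in self.shared.values() for s in ss if s is not None]
        return max(scores) if scores else float("-inf")


def derive_indirect(pairs: Sequence[GenePair]) -> list[IndirectAssociation]:
    """Join aggregated pairs through shared partners.

    Each returned association is symmetric in (key_a, key_b) — keys are
    stored in lexicographic order — and lists every shared partner once,
    even when several edge classes support it.
    """
    out_edges: dict[str, dict[str, float]] = defaultdict(dict)  # A -> {Z: best score}
    in_edges: dict[str, dict[str, float]] = defaultdict(dict)  # A <- {Z: best score}
    bind_edges: dict[str, dict[str, float]] = defaultdict(dict)

    def keep_best(d: dict[str, float], k: str, s) -> None:
        s = float("-inf") if s is None else s
        if k not in d or s > d[k]:
            d[k] = s

    capture_pairs: dict[tuple[str, str], dict[str, list[float]]] = defaultdict(dict)
    for p in pairs:
        if p.cls in _REGULATORY:
            keep_best(out_edges[p.key_a], p.key_b, p.agg_score)
            keep_best(in_edges[p.key_b], p.key_a, p.agg_score)
        elif p.cls == "binding":
            keep_best(bind_edges[p.key_a], p.key_b, p.agg_score)
            keep_best(bind_edges[p.key_b], p.key_a, p.agg_score)
        elif p.cls == "coregulation_capture":
            ab = tuple(sorted((p.key_a, p.key_b)))
            for z in sorted(p.via):
                capture_pairs[ab].setdefault(z, []).append(
                    float("-inf") if p.agg_score is None else p.agg_score
                )

    assocs: dict[tuple[str, str, str], IndirectAssociation] = {}

    def add(kind: str, a: str, b: str, z: str, scores: Iterable[float]) -> None:
        a, b = sorted((a, b))
        rec = assocs.setdefault((kind, a, b), IndirectAssociation(kind, a, b))
        rec.shared.setdefault(z, []).extend(scores)

    def join(edges: dict[str, dict[str, float]], kind: str) -> None:
        genes = sorted(edges)
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                for z in sorted(set(edges[a]) & set(edges[b])):
                    if z in (a, b):
                        continue
                    add(kind, a, b, z, [edges[a][z], edges[b][z]])

    join(out_edges, "coregulation")
    join(in_edges, "common_regulator")
    join(bind_edges, "common_binding_partner")
    for (a, b), zs in capture_pairs.items():
        for z, scores in zs.items():
            if z not in (a, b):
                add("coregulation", a, b, z, scores)
    return sorted(assocs.values(), key=lambda r: (r.kind, r.key_a, r.key_b))


def rank_associations(assocs: Sequence[IndirectAssociation]) -> list[IndirectAssociation]:
    """Order by number of shared partners, then best supporting edge score,
    then lexicographic keys — deterministic across runs."""
    return sorted(
        assocs,
        key=lambda r: (-r.n_shared, -r.best_score, r.kind, r.key_a, r.key_b),
    )


def associations_table(assocs: Iterable[IndirectAssociation]):
    import pandas as pd

    rows = [
        {
            "key_a": r.key_a,
            "key_b": r.key_b,
            "kind": r.kind,
            "n_shared": r.n_shared,
            "shared_list": ",".join(sorted(r.shared)),
            "hypothetical": r.hypothetical,
        }
        for r in assocs
    ]
    return pd.DataFrame(
        rows, columns=["key_a", "key_b", "kind", "n_shared", "shared_list", "hypothetical"]
    )


def write_sif(assocs: Iterable[IndirectAssociation], path) -> None:
    """SIF-style edge list (``key_a<TAB>kind<TAB>key_b``) for network tools."""
    lines = [f"{r.key_a}\t{r.kind}\t{r.key_b}" for r in assocs]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
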