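"""Pairwise abstraction: typed gene pairs from (refined) event structures.

Every unordered pair of distinct gene mentions inside one event structure
is a candidate association.  A pair is classified at the lowest common
ancestor (LCA) event of its two mentions:

1. both direct Themes of one binding event -> **binding** (undirected);
2. otherwise the LCA is regulation-class with one gene on the Cause side
   and one on the Theme side -> **regulation**, directed Cause-side gene
   -> Theme-side gene;
3. a Cause-side gene reached as the *Theme* of a nested event (e.g. G2 in
   ``Reg(C:Reg(C:G1, T:G2), T:G3)``) only regulates indirectly -> the pair
   is reclassified **indirect_regulation** (a Cause-side gene reached as a
   nested *Cause* — G1 above — remains a plain regulator);
4. a Theme-side gene reached through a nested *Cause* argument (G2 in
   ``Reg(C:G1, T:Reg(C:G2, T:G3))``) cannot convincingly be paired with the
   outer Cause gene: the candidate is discarded, but retained as a
   **coregulation_capture** seed (G1 and G2 both regulate the inner Theme
   G3), which later feeds only the coregulation join of the indirect-
   association stage.

Seeds are aggregated across documents under a generalization scheme:
evidence pooled on (class, key_a, key_b), aggregate confidence is the mean
of the evidence scores, and categories come from the corpus-wide range of
aggregated scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .canonical import FamilyScheme, generalization_key
from .confidence import Categorizer, categorize, score_generalized
from .model import Document, EventTree, Gene
from .refine import RefinedEvent

PAIR_CLASSES = ("binding", "regulation", "indirect_regulation", "coregulation_capture")


@dataclass(frozen=True)
class PairSeed:
    """One candidate pair from a single event structure (mention level)."""

    a: Gene
    b: Gene
    cls: str
    directed: bool
    #: for coregulation_capture: the Theme-side genes both causes act on
    via: tuple[Gene, ...] = ()


@dataclass(frozen=True)
class Evidence:
    doc_id: str
    event_id: Optional[str]
    score: Optional[float]


@dataclass
class GenePair:
    """An aggregated, typed gene association under one generalization."""

    key_a: str
    key_b: str
    cls: str
    directed: bool
    evidence: list[Evidence] = field(default_factory=list)
    via: set[str] = field(default_factory=set)
    agg_score: Optional[float] = None
    category: str = "unscored"

    @property
    def n_evidence(self) -> int:
        return len(self.evidence)

    @property
    def best_evidence(self) -> Optional[Evidence]:
        scored = [e for e in self.evidence if e.score is not None]
        return max(scored, key=lambda e: e.score) if scored else None


def _leaves_with_trails(
    node: EventTree, trail: tuple[tuple[int, int, str], ...] = ()
) -> list[tuple[Gene, tuple[tuple[int, int, str], ...]]]:
    """Gene leaves with their (node_uid, arg_index, role) trail from the root."""
    out = []
    uid = id(node)
    for i, (role, child) in enumerate(node.args):
        step = trail + ((uid, i, role),)
        if isinstance(child, Gene):
            out.append((child, step))
        else:
            out.extend(_leaves_with_trails(child, step))
    return out


def _node_by_uid(root: EventTree, uid: int) -> EventTree:
    for n in root.iter_events():
        if id(n) == uid:
            return n
    raise KeyError(uid)


def extract_pairs(root: EventTree) -> list[PairSeed]:
    """Classify every candidate gene pair of one (refined) structure.

    Mentions with identical labels (self-regulation statements) yield no
    pair.  Unrefined input is accepted; refinement beforehand simply
    reduces the variety of structures this has to handle.
    """
    leaves = _leaves_with_trails(root)
    seeds: list[PairSeed] = []
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            g1, t1 = leaves[i]
            g2, t2 = leaves[j]
            if g1.label == g2.label:
                continue
            # divergence point: deepest shared event where the paths split
            k = 0
            while k < min(len(t1), len(t2)) and t1[k][:2] == t2[k][:2]:
                k += 1
            lca = _node_by_uid(root, t1[k][0])
            r1, r2 = t1[k][2], t2[k][2]
            if lca.type == "binding":
                a, b = sorted((g1, g2), key=lambda g: g.label)
                seeds.append(PairSeed(a, b, "binding", directed=False))
                continue
            # regulation-class LCA: one path enters the Cause slot, one the Theme slot
            if r1 == "Cause":
                gc, tc, gt, tt = g1, t1, g2, t2
            else:
                gc, tc, gt, tt = g2, t2, g1, t1
            cause_sub = tc[k + 1 :]
            theme_sub = tt[k + 1 :]
            if any(role == "Cause" for _, _, role in theme_sub):
                # Theme-side gene is a nested Cause: discard, keep as capture
                cause_uid = [uid for uid, _, role in theme_sub if role == "Cause"][-1]
                holder = _node_by_uid(root, cause_uid)
                via = _theme_side_genes(holder)
                a, b = sorted((gc, gt), key=lambda g: g.label)
                seeds.append(PairSeed(a, b, "coregulation_capture", directed=False, via=via))
                continue
            indirect = bool(cause_sub) and cause_sub[-1][2] == "Theme"
            cls = "indirect_regulation" if indirect else "regulation"
            seeds.append(PairSeed(gc, gt, cls, directed=True))
    return seeds


def _theme_side_genes(holder: EventTree) -> tuple[Gene, ...]:
    """Genes under the Theme arguments of the event whose Cause is captured."""
    out: list[Gene] = []
    for role, child in holder.args:
        if role != "Theme":
            continue
        if isinstance(child, Gene):
            out.append(child)
        else:
            out.extend(child.genes())
    return tuple(out)


def aggregate_pairs(
    docs: Sequence[Document],
    refined: dict[str, list[RefinedEvent]],
    scheme: Union[str, FamilyScheme] = "canonical",
    bin_mode: str = "range",
    min_score: Optional[float] = None,
) -> list[GenePair]:
    """Merge pair seeds across a corpus under a generalization scheme.

    Seeds whose two keys coincide under the scheme (e.g. homolog pairs
    merged by a family) are dropped; binding and capture pairs store their
    keys in lexicographic order, regulation classes keep the a->b
    orientation.  Each pair's aggregate confidence is the mean of its
    evidence scores; categories are assigned from the corpus-wide range of
    aggregated scores (five equal-width bins by default).
    """
    by_doc = {d.doc_id: d for d in docs}
    merged: dict[tuple[str, str, str], GenePair] = {}
    for doc_id, events in refined.items():
        mentions = by_doc[doc_id].mention_map()

        def key_of(g: Gene) -> Optional[str]:
            if g.mention_id is not None and g.mention_id in mentions:
                m = mentions[g.mention_id]
                if not m.canonical:
                    return None  # uncanonicalizable, excluded
                return generalization_key(m, scheme)
            return g.label.lower()

        for r in events:
            for seed in extract_pairs(r.structure):
                ka, kb = key_of(seed.a), key_of(seed.b)
                if ka is None or kb is None or ka == kb:
                    continue
                if not seed.directed and ka > kb:
                    ka, kb = kb, ka
                gp = merged.setdefault(
                    (seed.cls, ka, kb),
                    GenePair(key_a=ka, key_b=kb, cls=seed.cls, directed=seed.directed),
                )
                gp.evidence.append(Evidence(doc_id, r.original_id, r.norm_score))
                for v in seed.via:
                    kv = key_of(v)
                    if kv is not None:
                        gp.via.add(kv)

    pairs = sorted(merged.values(), key=lambda p: (p.cls, p.key_a, p.key_b))
    for p in pairs:
        p.agg_score = score_generalized([e.score for e in p.evidence])
    scored = [p.agg_score for p in pairs if p.agg_score is not None]
    cat: Categorizer = categorize(scored, mode=bin_mode) if scored else Categorizer(edges=())
    for p in pairs:
        p.category = cat.label(p.agg_score)
    if min_score is not None:
        pairs = [p for p in pairs if p.agg_score is not None and p.agg_score >= min_score]
    return pairs


def pairs_table(pairs: Iterable[GenePair]):
    """Export-ready table (TSV via ``DataFrame.to_csv``)."""
    import pandas as pd

    rows = []
    for p in pairs:
        best = p.best_evidence
        rows.append(
            {
                "key_a": p.key_a,
                "key_b": p.key_b,
                "class": p.cls,
                "direction": "a>b" if p.directed else "a-b",
                "n_evidence": p.n_evidence,
                "agg_score": p.agg_score,
                "category": p.category,
                "best_doc": best.doc_id if best else "",
                "best_event": best.event_id if best else "",
                "via": ",".join(sorted(p.via)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "key_a",
            "key_b",
            "class",
            "direction",
            "n_evidence",
            "agg_score",
            "category",
            "best_doc",
            "best_event",
            "via",
        ],
    )
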