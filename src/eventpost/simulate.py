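"""Synthetic standoff corpora with planted ground truth.

The generator emits complete corpora in the standoff dialect of
:mod:`eventpost.standoff` — document text, entities, events, confidence
sidecars, a family-scheme table and an affix lexicon — together with a
``ground_truth.json`` holding the answers every pipeline stage should
recover: planted canonical symbols, refined structures, typed gene pairs
and indirect associations.

Structures are drawn from a mixture over signature patterns whose default
weights follow the prevalence of refined patterns in large-scale event
data (a single-gene physical event accounts for roughly 59% of
occurrences, two-gene regulations and bindings most of the rest, and the
three nested indirect patterns are rare at ~0.2% each).  To exercise the
refinement stage, removable chains of single-argument regulations are
inserted below regulation-class parents with configurable probability;
mention surfaces are optionally decorated with affixes ("human mec1
subunit") that canonicalization must strip.

Ground truth is computed by intentionally naive, separate walkers (literal
re-statements of the refinement table and the pairwise steps), not by the
package's main implementations, so pipeline tests are a genuine
dual-route check.  Output is byte-identical for a fixed seed.

The sentence text is a deterministic token template — linguistic realism
is not the goal, offset correctness is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .brackets import print_bracket
from .canonical import AffixLexicon, FamilyScheme
from .model import Document, EventOccurrence, EventTree, Gene, GeneMention, REGULATION_TYPES
from .standoff import write_corpus

#: Default pattern mixture (refined-shape prevalence; weights are
#: normalized at sampling time).
DEFAULT_MIXTURE: dict[str, float] = {
    "Phy(T:A)": 58.6,
    "*Reg(T:A)": 15.0,
    "*Reg(T:Phy(T:A))": 8.4,
    "Bind(T:A, T:B)": 8.0,
    "*Reg(C:A, T:B)": 4.7,
    "*Reg(C:A, T:Phy(T:B))": 3.8,
    "*Reg(C:*Reg(T:Phy(T:A)), T:Phy(T:B))": 0.2,
    "*Reg(C:Phy(T:A), T:B)": 0.2,
    "*Reg(C:Phy(T:A), T:Phy(T:B))": 0.2,
}

#: (symbol, family-or-None) — a small pool of real-looking gene symbols
#: with partial family coverage, so coverage statistics are non-trivial.
DEFAULT_GENE_POOL: list[tuple[str, Optional[str]]] = [
    ("mec1", "fam01"), ("atr", "fam01"), ("atm", "fam01"),
    ("rad9", "fam02"), ("rad53", "fam03"), ("chk2", "fam03"),
    ("esr1", "fam04"), ("esr2", "fam04"), ("mapk1", "fam05"),
    ("mapk3", "fam05"), ("akt1", "fam06"), ("egf", "fam07"),
    ("egfr", "fam07"), ("brca1", "fam08"), ("cdc2", "fam09"),
    ("cdk1", "fam09"), ("fos", "fam10"), ("jun", "fam10"),
    ("p53", None), ("il2", None), ("nfkb1", None), ("p55", None),
    ("thrombin", None), ("myc", None), ("hog1", None),
]

_PHYSICAL = ("gene_expression", "transcription", "localization", "protein_catabolism", "phosphorylation")
_REG = ("regulation", "positive_regulation", "negative_regulation")

_TRIGGERS = {
    "gene_expression": "expression",
    "transcription": "transcription",
    "localization": "localization",
    "protein_catabolism": "degradation",
    "phosphorylation": "phosphorylation",
    "binding": "binding",
    "regulation": "modulates",
    "positive_regulation": "activates",
    "negative_regulation": "inhibits",
}


class ConfigError(ValueError):
    pass


@dataclass
class ScoreModel:
    """Gaussian raw-margin model per classifier kind."""

    trigger_mean: float = 0.8
    trigger_sd: float = 1.1
    argument_mean: float = 0.5
    argument_sd: float = 0.9


@dataclass
class GeneratorConfig:
    n_documents: int = 100
    events_per_doc: int = 3
    pattern_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    gene_pool: list[tuple[str, Optional[str]]] = field(
        default_factory=lambda: list(DEFAULT_GENE_POOL)
    )
    score_model: ScoreModel = field(default_factory=ScoreModel)
    #: probability of inserting a removable single-argument regulation chain
    #: below each regulation-class parent
    chain_prob: float = 0.3
    max_chain_len: int = 2
    #: probability of decorating a mention surface with affixes
    decorate_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_documents < 0 or self.events_per_doc < 1:
            raise ConfigError("n_documents must be >=0 and events_per_doc >=1")
        weights = list(self.pattern_mixture.values())
        if not weights or any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ConfigError("pattern mixture needs positive weights")
        if len(self.gene_pool) < 4:
            raise ConfigError("gene pool too small")


# ---------------------------------------------------------------------------
# pattern parsing / instantiation


def _parse_pattern(s: str) -> Union[EventTree, Gene]:
    """Parse a signature pattern (``*Reg``/``Phy``/``Bind`` heads, A/B leaves)."""
    pos = 0

    def node() -> Union[EventTree, Gene]:
        nonlocal pos
        while s[pos] == " ":
            pos += 1
        start = pos
        while pos < len(s) and s[pos] not in "(),:":
            pos += 1
        head = s[start:pos].strip()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            args = []
            while s[pos] != ")":
                while s[pos] in " ,":
                    pos += 1
                role = {"C": "Cause", "T": "Theme"}[s[pos]]
                pos += 2  # role letter + ':'
                args.append((role, node()))
            pos += 1
            return EventTree(head, args)
        return Gene(head)

    tree = node()
    assert isinstance(tree, EventTree)
    return tree


def _instantiate(pattern: EventTree, rng: np.random.Generator, symbols: Sequence[str]) -> EventTree:
    """Concrete tree: sample event types per head, distinct genes per leaf."""
    n_genes = sum(1 for _ in _leaves(pattern))
    picks = list(rng.choice(len(symbols), size=n_genes, replace=False))
    it = iter(picks)

    def build(node: Union[EventTree, Gene]) -> Union[EventTree, Gene]:
        if isinstance(node, Gene):
            return Gene(symbols[int(next(it))])
        if node.type == "*Reg":
            t = _REG[int(rng.integers(3))]
        elif node.type == "Phy":
            t = _PHYSICAL[int(rng.integers(len(_PHYSICAL)))]
        else:
            t = "binding"
        return EventTree(t, [(r, build(c)) for r, c in node.args])

    out = build(pattern)
    assert isinstance(out, EventTree)
    return out


def _leaves(node: Union[EventTree, Gene]):
    if isinstance(node, Gene):
        yield node
    else:
        for _, c in node.args:
            yield from _leaves(c)


def _insert_chains(tree: EventTree, rng: np.random.Generator, prob: float, max_len: int) -> EventTree:
    """Insert removable single-argument regulation chains below regulation parents."""

    def build(node: Union[EventTree, Gene], parent_is_reg: bool) -> Union[EventTree, Gene]:
        if isinstance(node, Gene):
            return node
        new = EventTree(node.type, [])
        is_reg = node.type in REGULATION_TYPES
        for role, child in node.args:
            built = build(child, is_reg)
            if is_reg and role == "Theme" and rng.random() < prob:
                for _ in range(int(rng.integers(1, max_len + 1))):
                    built = EventTree(_REG[int(rng.integers(3))], [("Theme", built)])
            new.args.append((role, built))
        return new

    out = build(tree, False)
    assert isinstance(out, EventTree)
    return out


# ---------------------------------------------------------------------------
# naive ground-truth logic (kept deliberately separate from the main
# implementations in refine.py / pairs.py / indirect.py)

_NAIVE_RULES = {
    ("positive_regulation", "positive_regulation"): "positive_regulation",
    ("positive_regulation", "regulation"): "positive_regulation",
    ("regulation", "positive_regulation"): "positive_regulation",
    ("negative_regulation", "negative_regulation"): "positive_regulation",
    ("regulation", "regulation"): "regulation",
    ("negative_regulation", "regulation"): "negative_regulation",
    ("negative_regulation", "positive_regulation"): "negative_regulation",
    ("regulation", "negative_regulation"): "negative_regulation",
    ("positive_regulation", "negative_regulation"): "negative_regulation",
}


def naive_refine(tree: EventTree) -> EventTree:
    """Literal one-rule-at-a-time rewriter (outermost-first, one polarity change)."""
    work = tree.copy()
    budget_used = False
    while True:
        redexes: list[tuple[EventTree, int]] = []

        def collect(n: EventTree) -> None:
            if n.type in REGULATION_TYPES:
                for i, (role, child) in enumerate(n.args):
                    if (
                        role == "Theme"
                        and isinstance(child, EventTree)
                        and child.type in REGULATION_TYPES
                        and not any(r == "Cause" for r, _ in child.args)
                    ):
                        redexes.append((n, i))
            for role, child in [(r, c) for r, c in n.args if r == "Cause"] + [
                (r, c) for r, c in n.args if r == "Theme"
            ]:
                if isinstance(child, EventTree):
                    collect(child)

        collect(work)
        if not redexes:
            return work
        parent, i = redexes[0]
        inner = parent.args[i][1]
        assert isinstance(inner, EventTree)
        new_type = _NAIVE_RULES[(parent.type, inner.type)]
        if new_type != parent.type:
            if budget_used:
                new_type = "regulation"
            budget_used = True
        inner_theme = [c for r, c in inner.args if r == "Theme"][0]
        parent.type = new_type
        parent.args[i] = ("Theme", inner_theme)


def naive_pairs(tree: EventTree) -> list[dict]:
    """Literal step 1-3 pair walker over one structure.

    Returns dicts with mention-level genes:
    ``{"cls", "a", "b", "directed", "via"}``.
    """
    # gene leaves with explicit ancestor chains [(event, role-of-child), ...]
    chains: list[tuple[Gene, list[tuple[EventTree, str]]]] = []

    def walk(n: EventTree, anc: list[tuple[EventTree, str]]) -> None:
        for role, child in n.args:
            if isinstance(child, Gene):
                chains.append((child, anc + [(n, role)]))
            else:
                walk(child, anc + [(n, role)])

    walk(tree, [])
    out = []
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            g1, c1 = chains[i]
            g2, c2 = chains[j]
            if g1.label == g2.label:
                continue
            # deepest shared ancestor event
            k = 0
            while k < min(len(c1), len(c2)) and c1[k][0] is c2[k][0]:
                k += 1
            lca, role1 = c1[k - 1]
            if lca.type == "binding":
                a, b = sorted((g1, g2), key=lambda g: g.label)
                out.append({"cls": "binding", "a": a, "b": b, "directed": False, "via": ()})
                continue
            if role1 == "Cause":
                gc, cc, gt, ct = g1, c1, g2, c2
            else:
                gc, cc, gt, ct = g2, c2, g1, c1
            below_c = cc[k:]  # entries strictly below the LCA slot
            below_t = ct[k:]
            if any(role == "Cause" for _, role in below_t):
                # theme-side gene reached through a nested Cause: discard
                holder = [ev for ev, role in below_t if role == "Cause"][-1]
                via = []
                for role, child in holder.args:
                    if role == "Theme":
                        via.extend(_leaves(child))
                a, b = sorted((gc, gt), key=lambda g: g.label)
                out.append(
                    {"cls": "coregulation_capture", "a": a, "b": b, "directed": False, "via": tuple(via)}
                )
                continue
            if below_c and below_c[-1][1] == "Theme":
                cls = "indirect_regulation"
            else:
                cls = "regulation"
            out.append({"cls": cls, "a": gc, "b": gt, "directed": True, "via": ()})
    return out


def naive_associations(pairs: list[dict]) -> list[dict]:
    """Triple-loop join over aggregated pair dicts (keys ``cls,a,b,via``)."""
    reg = {(p["a"], p["b"]) for p in pairs if p["cls"] in ("regulation", "indirect_regulation")}
    bind = set()
    for p in pairs:
        if p["cls"] == "binding":
            bind.add((p["a"], p["b"]))
            bind.add((p["b"], p["a"]))
    genes = sorted({g for ab in reg | bind for g in ab})
    out = {}

    def add(kind, a, b, z):
        a, b = sorted((a, b))
        out.setdefault((kind, a, b), set()).add(z)

    for a in genes:
        for b in genes:
            if a >= b:
                continue
            for z in genes:
                if z in (a, b):
                    continue
                if (a, z) in reg and (b, z) in reg:
                    add("coregulation", a, b, z)
                if (z, a) in reg and (z, b) in reg:
                    add("common_regulator", a, b, z)
                if (a, z) in bind and (b, z) in bind:
                    add("common_binding_partner", a, b, z)
    for p in pairs:
        if p["cls"] == "coregulation_capture":
            for z in p["via"]:
                if z not in (p["a"], p["b"]):
                    add("coregulation", p["a"], p["b"], z)
    return [
        {"kind": k, "key_a": a, "key_b": b, "shared": sorted(zs)}
        for (k, a, b), zs in sorted(out.items())
    ]


# ---------------------------------------------------------------------------
# corpus assembly


def _decorate(symbol: str, rng: np.random.Generator, lex: AffixLexicon) -> str:
    surface = symbol if rng.random() < 0.5 else symbol.capitalize()
    pre = sorted(lex.prefixes)
    suf = sorted(lex.suffixes)
    if rng.random() < 0.5:
        surface = f"{pre[int(rng.integers(len(pre)))]} {surface}"
    else:
        surface = f"{surface} {suf[int(rng.integers(len(suf)))]}"
    return surface


def _build_document(
    doc_id: str,
    trees: list[EventTree],
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    lex: AffixLexicon,
) -> tuple[Document, dict[str, str]]:
    """Linearize trees into text + annotations; returns (doc, mention->symbol)."""
    tokens: list[str] = []
    pos = 0

    def emit(tok: str) -> tuple[int, int]:
        nonlocal pos
        start = pos
        tokens.append(tok)
        pos += len(tok) + 1  # single-space joined
        return start, start + len(tok)

    doc = Document(doc_id=doc_id, text="")
    planted: dict[str, str] = {}
    m_counter = e_counter = 0
    sm = cfg.score_model

    def build(node: Union[EventTree, Gene]) -> str:
        nonlocal m_counter, e_counter
        if isinstance(node, Gene):
            m_counter += 1
            mid = f"T{m_counter}"
            surface = (
                _decorate(node.label, rng, lex)
                if rng.random() < cfg.decorate_prob
                else (node.label if rng.random() < 0.5 else node.label.capitalize())
            )
            start, end = emit(surface)
            doc.mentions.append(GeneMention(mid, start, end, surface))
            planted[mid] = node.label
            return mid
        ttext = _TRIGGERS[node.type]
        tstart, tend = emit(ttext)
        arg_ids = [(role, build(child)) for role, child in node.args]
        e_counter += 1
        eid = f"E{e_counter}"
        trigger_score = float(rng.normal(sm.trigger_mean, sm.trigger_sd))
        arg_scores = [float(rng.normal(sm.argument_mean, sm.argument_sd)) for _ in arg_ids]
        doc.events.append(
            EventOccurrence(eid, node.type, tstart, tend, ttext, arg_ids, trigger_score, arg_scores)
        )
        node.event_id = eid
        return eid

    for tree in trees:
        build(tree)
        emit(".")
    doc.text = " ".join(tokens)
    return doc, planted


def generate(
    config: GeneratorConfig, out_dir: Optional[Union[str, Path]] = None
) -> tuple[list[Document], dict]:
    """Generate a corpus and its ground truth.

    When ``out_dir`` is given, writes the standoff files, the confidence
    sidecars, ``families.tsv``, ``lexicon.yaml`` and ``ground_truth.json``
    there; always returns ``(documents, ground_truth)``.
    """
    rng = np.random.default_rng(config.seed)
    lex = AffixLexicon()
    patterns = sorted(config.pattern_mixture)
    weights = np.array([config.pattern_mixture[p] for p in patterns], dtype=float)
    weights /= weights.sum()
    symbols = [s for s, _ in config.gene_pool]
    scheme = FamilyScheme(
        name="families",
        mapping={s: f for s, f in config.gene_pool if f is not None},
        provenance="synthetic",
    )

    docs: list[Document] = []
    doc_patterns: dict[str, list[str]] = {}
    doc_trees: dict[str, list[EventTree]] = {}
    planted_all: dict[str, dict[str, str]] = {}
    for d in range(config.n_documents):
        doc_id = f"doc{d:05d}"
        trees, chosen = [], []
        for _ in range(config.events_per_doc):
            p = patterns[int(rng.choice(len(patterns), p=weights))]
            chosen.append(p)
            tree = _instantiate(_parse_pattern(p), rng, symbols)
            tree = _insert_chains(tree, rng, config.chain_prob, config.max_chain_len)
            trees.append(tree)
        doc, planted = _build_document(doc_id, trees, rng, config, lex)
        docs.append(doc)
        doc_patterns[doc_id] = chosen
        doc_trees[doc_id] = trees
        planted_all[doc_id] = planted

    # ground truth via the naive walkers, at the canonical generalization
    gt_docs = {}
    merged_pairs: dict[tuple[str, str, str], dict] = {}
    for doc in docs:
        planted = planted_all[doc.doc_id]
        refined_brackets = []
        for tree in doc_trees[doc.doc_id]:
            # relabel leaves by planted canonical symbol for ground truth
            refined = naive_refine(tree)
            refined_brackets.append(print_bracket(refined))
            for seed in naive_pairs(refined):
                ka, kb = seed["a"].label, seed["b"].label
                if not seed["directed"] and ka > kb:
                    ka, kb = kb, ka
                rec = merged_pairs.setdefault(
                    (seed["cls"], ka, kb),
                    {"cls": seed["cls"], "key_a": ka, "key_b": kb, "n_evidence": 0, "via": set()},
                )
                rec["n_evidence"] += 1
                rec["via"].update(g.label for g in seed["via"])
        gt_docs[doc.doc_id] = {
            "patterns": doc_patterns[doc.doc_id],
            "refined": refined_brackets,
            "canonical": planted,
        }

    pair_dicts = [
        {"cls": r["cls"], "a": r["key_a"], "b": r["key_b"], "via": sorted(r["via"])}
        for r in merged_pairs.values()
    ]
    gt = {
        "config": {
            "n_documents": config.n_documents,
            "events_per_doc": config.events_per_doc,
            "seed": config.seed,
        },
        "docs": gt_docs,
        "pairs": sorted(
            (
                {
                    "cls": r["cls"],
                    "key_a": r["key_a"],
                    "key_b": r["key_b"],
                    "n_evidence": r["n_evidence"],
                    "via": sorted(r["via"]),
                }
                for r in merged_pairs.values()
            ),
            key=lambda r: (r["cls"], r["key_a"], r["key_b"]),
        ),
        "associations": naive_associations(pair_dicts),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_corpus(docs, out_dir)
        scheme.to_tsv(out_dir / "families.tsv")
        lex.to_yaml(out_dir / "lexicon.yaml")
        (out_dir / "ground_truth.json").write_text(
            json.dumps(gt, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    return docs, gt
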