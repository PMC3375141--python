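"""The nested-regulation rewrite system: rules, budget, invariants."""

import numpy as np
import pytest

from eventpost import compose_polarity, parse_bracket, print_bracket, refine, signature
from eventpost.model import EventTree, Gene, REGULATION_TYPES
from eventpost.simulate import naive_refine


def test_compose_polarity_short_and_long_names():
    assert compose_polarity("Neg", "Neg") == ("Pos", True)
    assert compose_polarity("positive_regulation", "positive_regulation") == (
        "positive_regulation",
        False,
    )
    assert compose_polarity("regulation", "regulation") == ("regulation", False)
    with pytest.raises(ValueError):
        compose_polarity("binding", "Pos")


@pytest.mark.parametrize(
    "chain, expected, n_changes",
    [
        ("Pos(C:AngII, T:Pos(T:MAPK))", "Positive-Regulation(C:AngII, T:MAPK)", 0),
        ("Neg(C:E2, T:Neg(T:p21))", "Positive-Regulation(C:E2, T:p21)", 1),
        ("Reg(C:CaM, T:Pos(T:HSFs))", "Positive-Regulation(C:CaM, T:HSFs)", 1),
        ("Pos(C:DtRE, T:Neg(T:CAB2))", "Negative-Regulation(C:DtRE, T:CAB2)", 1),
        # double polarity change: the second is forced to unspecified
        ("Neg(C:A, T:Neg(T:Neg(T:B)))", "Regulation(C:A, T:B)", 1),
    ],
)
def test_refine_chains(chain, expected, n_changes):
    r = refine(parse_bracket(chain))
    assert print_bracket(r.structure) == expected
    assert r.polarity_changes_used == n_changes


def test_forced_unspecified_flag():
    r = refine(parse_bracket("Neg(C:A, T:Neg(T:Neg(T:B)))"))
    assert r.forced_unspecified
    r2 = refine(parse_bracket("Neg(C:E2, T:Neg(T:p21))"))
    assert not r2.forced_unspecified


def test_non_regulation_events_untouched():
    for s in ["Bind(T:A, T:B)", "Phos(T:A)"]:
        r = refine(parse_bracket(s))
        assert print_bracket(r.structure) == print_bracket(r.original)
        assert r.removed == []


def test_nested_regulation_with_cause_not_removed():
    # the inner regulation carries its own regulator: not a removable unit
    s = "Pos(C:Thrombin, T:Pos(C:EGF, T:Phosphorylation(T:Akt)))"
    r = refine(parse_bracket(s))
    assert print_bracket(r.structure) == print_bracket(parse_bracket(s))


def test_original_preserved_and_removal_provenance():
    r = refine(parse_bracket("Pos(C:A, T:Pos(T:Pos(T:B)))"))
    assert print_bracket(r.original) == "Positive-Regulation(C:A, T:Positive-Regulation(T:Positive-Regulation(T:B)))"
    assert [t for _, t in r.removed] == ["positive_regulation", "positive_regulation"]


def _random_structure(rng: np.random.Generator, depth: int) -> EventTree:
    """Random valid event structure biased toward regulation chains."""
    regs = sorted(REGULATION_TYPES)
    roll = rng.random()
    if depth <= 0 or roll < 0.15:
        return EventTree("phosphorylation", [("Theme", Gene(f"g{rng.integers(6)}"))])
    if roll < 0.25:
        k = int(rng.integers(1, 4))
        return EventTree("binding", [("Theme", Gene(f"g{rng.integers(6)}")) for _ in range(k)])
    t = regs[int(rng.integers(3))]
    theme = (
        Gene(f"g{rng.integers(6)}") if rng.random() < 0.3 else _random_structure(rng, depth - 1)
    )
    args = [("Theme", theme)]
    if rng.random() < 0.35:
        cause = (
            Gene(f"g{rng.integers(6)}")
            if rng.random() < 0.5
            else _random_structure(rng, depth - 2)
        )
        args.insert(0, ("Cause", cause))
    return EventTree(t, args)


def _has_redex(node):
    for e in node.iter_events():
        if e.type in REGULATION_TYPES:
            for role, child in e.args:
                if (
                    role == "Theme"
                    and isinstance(child, EventTree)
                    and child.type in REGULATION_TYPES
                    and not child.causes()
                ):
                    return True
    return False


def _gene_multiset(node):
    return sorted(g.label for g in node.genes())


def test_refinement_invariants_on_random_chains():
    """Idempotence, fixpoint characterization, gene preservation and
    polarity-budget bookkeeping over seeded random structures."""
    rng = np.random.default_rng(20240917)
    for _ in range(2000):
        tree = _random_structure(rng, depth=5)
        r = refine(tree)
        # fixpoint: no removable nested regulation remains, and a structure
        # is unchanged iff it had none to begin with
        assert not _has_redex(r.structure)
        unchanged = print_bracket(r.structure) == print_bracket(r.original)
        assert unchanged == (not _has_redex(r.original))
        # idempotence: refining again applies zero further rules
        r2 = refine(r.structure)
        assert print_bracket(r2.structure) == print_bracket(r.structure)
        assert r2.removed == []
        # gene multiset preserved
        assert _gene_multiset(r.structure) == _gene_multiset(r.original)
        # at most one real polarity change per root structure
        assert r.polarity_changes_used in (0, 1)


def test_refine_matches_naive_rewriter():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        tree = _random_structure(rng, depth=4)
        assert print_bracket(refine(tree).structure) == print_bracket(naive_refine(tree))


def test_corpus_refinement_reduces_structure_variety(small_corpus):
    from eventpost import refine_corpus
    from eventpost.model import to_tree

    docs, _ = small_corpus
    before = {signature(to_tree(d, e)) for d in docs for e in d.root_events()}
    refined = refine_corpus(docs)
    after = {signature(r.structure) for ev in refined.values() for r in ev}
    assert len(after) <= len(before)


def test_refined_corpus_is_valid_standoff(small_corpus):
    """Refined structures re-serialize to constraint-clean standoff."""
    from eventpost import refine_corpus, refined_document, read_standoff, write_standoff
    from eventpost.model import to_tree, tree_equal

    docs, _ = small_corpus
    refined = refine_corpus(docs)
    for doc in docs[:10]:
        rdoc = refined_document(doc, refined[doc.doc_id])
        a1, a2 = write_standoff(rdoc)
        again = read_standoff(a1, a2, rdoc.text, doc_id=rdoc.doc_id)  # validates
        for r, e in zip(refined[doc.doc_id], again.root_events()):
            stripped = r.structure  # labels are surfaces in both trees
            assert tree_equal(stripped, to_tree(again, e))
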