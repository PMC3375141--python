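"""Pairwise abstraction: candidate classification and aggregation."""

import numpy as np
import pytest

from eventpost import aggregate_pairs, extract_pairs, parse_bracket, refine_corpus
from eventpost.canonical import FamilyScheme, canonicalize_corpus
from eventpost.simulate import naive_pairs


def _seed_set(seeds):
    return {
        (s.cls, s.a.label, s.b.label, s.directed, tuple(sorted(g.label for g in s.via)))
        for s in seeds
    }


def test_cause_chain_example():
    seeds = _seed_set(
        extract_pairs(parse_bracket("Pos(C:Thrombin, T:Pos(C:EGF, T:Phos(T:Akt)))"))
    )
    assert seeds == {
        ("regulation", "Thrombin", "Akt", True, ()),
        ("regulation", "EGF", "Akt", True, ()),
        ("coregulation_capture", "EGF", "Thrombin", False, ("Akt",)),
    }


def test_nested_cause_regulation_example():
    seeds = _seed_set(extract_pairs(parse_bracket("Reg(C:Reg(C:G1, T:G2), T:G3)")))
    assert seeds == {
        ("regulation", "G1", "G3", True, ()),
        ("indirect_regulation", "G2", "G3", True, ()),
        ("regulation", "G1", "G2", True, ()),
    }


def test_binding_under_regulation():
    seeds = _seed_set(
        extract_pairs(parse_bracket("Pos(C:IL-2, T:Bind(T:NF-κB, T:p55))"))
    )
    assert seeds == {
        ("binding", "NF-κB", "p55", False, ()),
        ("regulation", "IL-2", "NF-κB", True, ()),
        ("regulation", "IL-2", "p55", True, ()),
    }


def test_single_gene_and_self_pairs():
    assert extract_pairs(parse_bracket("Phos(T:Akt)")) == []
    # identical gene twice: self-regulation yields no pair
    assert extract_pairs(parse_bracket("Pos(C:Akt, T:Phos(T:Akt))")) == []


TABLE_PATTERNS = [
    ("Phos(T:A)", set()),
    ("Reg(T:A)", set()),
    ("Reg(T:Phos(T:A))", set()),
    ("Bind(T:A, T:B)", {("binding", "A", "B")}),
    ("Reg(C:A, T:B)", {("regulation", "A", "B")}),
    ("Reg(C:A, T:Phos(T:B))", {("regulation", "A", "B")}),
    ("Reg(C:Reg(T:Phos(T:A)), T:Phos(T:B))", {("indirect_regulation", "A", "B")}),
    ("Reg(C:Phos(T:A), T:B)", {("indirect_regulation", "A", "B")}),
    ("Reg(C:Phos(T:A), T:Phos(T:B))", {("indirect_regulation", "A", "B")}),
]


@pytest.mark.parametrize("pattern, expected", TABLE_PATTERNS)
def test_prevalent_pattern_pair_classes(pattern, expected):
    """Each prevalent refined pattern yields its stated pair class:
    A×B binding, A>B regulation, A≫B indirect regulation."""
    got = {(s.cls, s.a.label, s.b.label) for s in extract_pairs(parse_bracket(pattern))}
    assert got == expected


def test_three_theme_binding_pairs_all():
    got = _seed_set(extract_pairs(parse_bracket("Bind(T:A, T:B, T:C)")))
    assert got == {
        ("binding", "A", "B", False, ()),
        ("binding", "A", "C", False, ()),
        ("binding", "B", "C", False, ()),
    }


def test_extract_matches_naive_walker_on_random_structures():
    from test_refine import _random_structure

    rng = np.random.default_rng(99)
    for _ in range(500):
        tree = _random_structure(rng, depth=3)
        got = _seed_set(extract_pairs(tree))
        want = {
            (
                s["cls"],
                s["a"].label,
                s["b"].label,
                s["directed"],
                tuple(sorted(g.label for g in s["via"])),
            )
            for s in naive_pairs(tree)
        }
        assert got == want


def _mini_corpus(bracket_by_doc):
    """Documents built from bracket strings via the generator machinery."""
    from eventpost.canonical import AffixLexicon
    from eventpost.simulate import GeneratorConfig, _build_document

    rng = np.random.default_rng(0)
    cfg = GeneratorConfig(n_documents=0, decorate_prob=0.0)
    docs = []
    for doc_id, brackets in bracket_by_doc.items():
        trees = [parse_bracket(b) for b in brackets]
        doc, _ = _build_document(doc_id, trees, rng, cfg, AffixLexicon())
        docs.append(doc)
    return docs


def test_aggregate_merges_evidence_and_keeps_directions_distinct():
    docs = _mini_corpus(
        {
            "d1": ["Pos(C:Mec1, T:Phos(T:RAD9))"],
            "d2": ["Neg(C:mec1, T:rad9)"],
            "d3": ["Reg(C:RAD9, T:Mec1)"],
        }
    )
    canonicalize_corpus(docs)
    from eventpost import score_corpus

    score_corpus(docs)
    pairs = aggregate_pairs(docs, refine_corpus(docs))
    by_key = {(p.cls, p.key_a, p.key_b): p for p in pairs}
    fwd = by_key[("regulation", "mec1", "rad9")]
    rev = by_key[("regulation", "rad9", "mec1")]
    assert fwd.n_evidence == 2  # two documents, one merged pair
    assert rev.n_evidence == 1  # opposite direction stays distinct
    assert fwd.agg_score == pytest.approx(
        np.mean([e.score for e in fwd.evidence])
    )


def test_family_scheme_pools_homolog_evidence():
    docs = _mini_corpus(
        {
            "d1": ["Pos(C:mec1, T:rad9)"],
            "d2": ["Pos(C:atr, T:rad9)"],
        }
    )
    scheme = FamilyScheme("hg", {"mec1": "F42", "atr": "F42"})
    canonicalize_corpus(docs, schemes=[scheme])
    from eventpost import score_corpus

    score_corpus(docs)
    refined = refine_corpus(docs)
    canonical_pairs = [p for p in aggregate_pairs(docs, refined) if p.cls == "regulation"]
    assert len(canonical_pairs) == 2
    family_pairs = [p for p in aggregate_pairs(docs, refined, scheme) if p.cls == "regulation"]
    assert len(family_pairs) == 1
    assert family_pairs[0].key_a == "F42" and family_pairs[0].n_evidence == 2


def test_pair_keys_always_differ_and_no_duplicate_evidence(small_corpus):
    docs, _ = small_corpus
    canonicalize_corpus(docs)
    from eventpost import score_corpus

    score_corpus(docs)
    refined = refine_corpus(docs)
    pairs = aggregate_pairs(docs, refined)
    n_seeds = sum(
        len(extract_pairs(r.structure)) for ev in refined.values() for r in ev
    )
    assert all(p.key_a != p.key_b for p in pairs)
    assert sum(p.n_evidence for p in pairs) <= n_seeds
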