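"""Margin normalization, min-aggregation, binning and ranking."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eventpost import (
    CATEGORY_ORDER,
    categorize,
    fit_normalization,
    rank_events,
    score_generalized,
    score_occurrence,
)
from eventpost.confidence import DegenerateCorpusError, NormalizationParams
from eventpost.model import Document, EventOccurrence


def _doc(trigger_scores, arg_scores):
    doc = Document("d", "x")
    for i, (t, a) in enumerate(zip(trigger_scores, arg_scores)):
        doc.events.append(
            EventOccurrence(f"E{i}", "phosphorylation", 0, 1, "x", [("Theme", "T1")], t, [a])
        )
    return doc


def test_fit_normalization_closed_form():
    doc = _doc([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
    params = fit_normalization([doc])
    assert params.trigger_mean == pytest.approx(2.0)
    assert params.trigger_sd == pytest.approx(math.sqrt(2.0 / 3.0))
    zs = [params.z(x, "trigger") for x in (1.0, 2.0, 3.0)]
    assert zs == pytest.approx([-1.224744871, 0.0, 1.224744871])
    # already standardized scores -> identity transform
    std = NormalizationParams(0.0, 1.0, 0.0, 1.0)
    assert std.z(0.73, "trigger") == 0.73


def test_fit_normalization_zero_mean_unit_sd(small_corpus):
    docs, _ = small_corpus
    params = fit_normalization(docs)
    trig = [params.z(e.trigger_score, "trigger") for d in docs for e in d.events]
    args = [params.z(s, "argument") for d in docs for e in d.events for s in e.arg_scores]
    import numpy as np

    assert np.mean(trig) == pytest.approx(0.0, abs=1e-12)
    assert np.std(trig) == pytest.approx(1.0, abs=1e-12)
    assert np.mean(args) == pytest.approx(0.0, abs=1e-12)
    assert np.std(args) == pytest.approx(1.0, abs=1e-12)


def test_degenerate_corpus_rejected():
    with pytest.raises(DegenerateCorpusError):
        fit_normalization([_doc([1.0, 1.0], [0.1, 0.2])])


def test_occurrence_score_is_component_minimum():
    params = NormalizationParams(0.0, 1.0, 0.0, 1.0)
    e = EventOccurrence(
        "E1", "binding", 0, 1, "x", [("Theme", "T1"), ("Theme", "T2")], 0.5, [0.2, 0.9]
    )
    assert score_occurrence(e, params) == 0.2
    e2 = EventOccurrence("E2", "phosphorylation", 0, 1, "x", [("Theme", "T1")], -1.0, [0.3])
    assert score_occurrence(e2, params) == -1.0
    e3 = EventOccurrence("E3", "phosphorylation", 0, 1, "x", [("Theme", "T1")], 0.7, [0.7])
    assert score_occurrence(e3, params) == 0.7


def test_events_missing_components_are_unscored_and_rank_last():
    params = NormalizationParams(0.0, 1.0, 0.0, 1.0)
    complete = EventOccurrence("E1", "phosphorylation", 0, 1, "x", [("Theme", "T1")], 0.1, [0.2])
    missing = EventOccurrence("E2", "phosphorylation", 0, 1, "x", [("Theme", "T1")], 0.9, None)
    score_occurrence(complete, params)
    score_occurrence(missing, params)
    assert missing.norm_score is None
    assert [e.event_id for e in rank_events([missing, complete])] == ["E1", "E2"]


def test_generalized_score_is_mean_excluding_unscored():
    assert score_generalized([0.2, 0.4]) == pytest.approx(0.3)
    assert score_generalized([0.7]) == 0.7
    assert score_generalized([-1.0, 1.0]) == 0.0
    assert score_generalized([None, 0.5, None]) == 0.5
    assert score_generalized([None, None]) is None


def test_range_binning_top_20pct():
    cat = categorize([-1.0, 1.0, 0.9, 0.0])
    assert cat.label(0.9) == "very_high"  # bin [0.6, 1.0]
    assert cat.label(-1.0) == "very_low"
    assert cat.label(1.0) == "very_high"
    assert cat.edges[4] == pytest.approx(0.6)


def test_uniform_grid_fills_bins_evenly():
    scores = [i / 99 * 7.0 - 2.0 for i in range(100)]
    cat = categorize(scores)
    from collections import Counter

    counts = Counter(cat.label(s) for s in scores)
    assert all(counts[lbl] == 20 for lbl in CATEGORY_ORDER)


def test_quantile_binning_balances_skewed_scores():
    scores = [0.0] * 0 + [float(i**2) for i in range(100)]
    cat = categorize(scores, mode="quantile")
    from collections import Counter

    counts = Counter(cat.label(s) for s in scores)
    assert max(counts.values()) - min(counts.values()) <= 2


def test_single_score_degenerate_range_is_average():
    cat = categorize([0.4, 0.4])
    assert cat.label(0.4) == "average"


def test_labels_order_consistent_with_scores():
    scores = [-2.0, -0.5, 0.0, 0.3, 1.7, 2.2]
    cat = categorize(scores)
    order = {lbl: i for i, lbl in enumerate(CATEGORY_ORDER)}
    labels = [cat.label(s) for s in sorted(scores)]
    assert [order[l] for l in labels] == sorted(order[l] for l in labels)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    trigger=st.floats(-5, 5),
    args=st.lists(st.floats(-5, 5), min_size=1, max_size=3),
    bump=st.floats(0.001, 2.0),
    which=st.integers(0, 3),
)
def test_monotonicity_of_min_aggregation(trigger, args, bump, which):
    """Raising any single component never lowers the occurrence score."""
    params = NormalizationParams(0.0, 1.0, 0.0, 1.0)

    def make(t, a):
        e = EventOccurrence(
            "E", "binding", 0, 1, "x", [("Theme", f"T{i}") for i in range(len(a))], t, list(a)
        )
        return score_occurrence(e, params)

    base = make(trigger, args)
    if which == 0:
        raised = make(trigger + bump, args)
    else:
        idx = (which - 1) % len(args)
        raised = make(trigger, [a + bump if i == idx else a for i, a in enumerate(args)])
    assert raised >= base


def test_normalization_invariant_under_trigger_shift(small_corpus):
    """Adding a constant to all raw trigger margins changes nothing."""
    import copy

    docs, _ = small_corpus
    docs_a = copy.deepcopy(docs[:10])
    docs_b = copy.deepcopy(docs[:10])
    for d in docs_b:
        for e in d.events:
            e.trigger_score += 17.5
    pa, pb = fit_normalization(docs_a), fit_normalization(docs_b)
    for da, db in zip(docs_a, docs_b):
        for ea, eb in zip(da.events, db.events):
            sa, sb = score_occurrence(ea, pa), score_occurrence(eb, pb)
            assert sa == pytest.approx(sb, abs=1e-9)
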