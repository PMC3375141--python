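"""Confidence normalization, aggregation, binning and ranking.

The upstream extractor scores each decision with an SVM margin: one score
for the event trigger and one per argument.  The two classifiers' margins
are not mutually comparable, so all scores in a corpus are z-scored to
zero mean and unit (population) standard deviation, separately per kind.
An event occurrence's confidence is the **minimum** of its normalized
component scores — a fuzzy-AND: every decision involved must be confident
for the event to rank high.  A generalized (cross-document) event scores
the arithmetic mean of its occurrences.

For presentation, aggregated scores are binned into five categories
(very_high .. very_low).  The default carves the observed confidence range
into five equal-width bins (the top 20% of the range is "very high");
a quantile mode (20% of events per bin) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import Document, EventOccurrence

CATEGORY_ORDER = ("very_low", "low", "average", "high", "very_high")


class DegenerateCorpusError(ValueError):
    """All raw scores of one kind are identical; no normalization exists."""


@dataclass(frozen=True)
class NormalizationParams:
    trigger_mean: float
    trigger_sd: float
    argument_mean: float
    argument_sd: float

    def z(self, raw: float, kind: str) -> float:
        if kind == "trigger":
            return (raw - self.trigger_mean) / self.trigger_sd
        if kind == "argument":
            return (raw - self.argument_mean) / self.argument_sd
        raise ValueError(f"unknown classifier kind {kind!r}")


def fit_normalization(docs: Iterable[Document]) -> NormalizationParams:
    """Fit per-kind z-score parameters over every raw margin in the corpus."""
    trig: list[float] = []
    arg: list[float] = []
    for doc in docs:
        for e in doc.events:
            if e.trigger_score is not None:
                trig.append(e.trigger_score)
            if e.arg_scores:
                arg.extend(s for s in e.arg_scores if s is not None)

    def fit(xs: list[float], kind: str) -> tuple[float, float]:
        if len(set(xs)) < 2:
            raise DegenerateCorpusError(
                f"need >=2 distinct {kind} scores to normalize, got {len(set(xs))}"
            )
        mean = float(np.mean(xs))
        sd = float(np.std(xs))  # population sd
        return mean, sd

    tm, ts = fit(trig, "trigger")
    am, asd = fit(arg, "argument")
    return NormalizationParams(tm, ts, am, asd)


def score_occurrence(e: EventOccurrence, params: NormalizationParams) -> Optional[float]:
    """Minimum normalized component score; sets and returns ``norm_score``.

    Events missing the trigger score or any argument score are left
    unscored (None) and rank last.
    """
    if e.trigger_score is None:
        e.norm_score = None
        return None
    if e.arguments and (
        e.arg_scores is None
        or len(e.arg_scores) != len(e.arguments)
        or any(s is None for s in e.arg_scores)
    ):
        e.norm_score = None
        return None
    components = [params.z(e.trigger_score, "trigger")]
    if e.arg_scores:
        components.extend(params.z(s, "argument") for s in e.arg_scores)
    e.norm_score = min(components)
    return e.norm_score


def score_corpus(docs: Iterable[Document], params: Optional[NormalizationParams] = None) -> NormalizationParams:
    """Fit (unless given) and apply occurrence scoring across a corpus."""
    docs = list(docs)
    if params is None:
        params = fit_normalization(docs)
    for doc in docs:
        for e in doc.events:
            score_occurrence(e, params)
    return params


def score_generalized(occurrence_scores: Sequence[Optional[float]]) -> Optional[float]:
    """Mean of the scored occurrences; None when nothing is scored.

    Unscored occurrences are excluded from the mean but still count as
    evidence for the generalized event.
    """
    scored = [s for s in occurrence_scores if s is not None]
    if not scored:
        return None
    return float(np.mean(scored))


@dataclass(frozen=True)
class Categorizer:
    """Maps aggregated confidence scores to the five category labels."""

    edges: tuple[float, ...]  # 6 ascending boundaries, or () when degenerate
    mode: str = "range"

    def label(self, score: Optional[float]) -> str:
        if score is None:
            return "unscored"
        if not self.edges:
            return "average"
        lo, hi = self.edges[0], self.edges[-1]
        if score <= lo:
            return CATEGORY_ORDER[0]
        if score >= hi:
            return CATEGORY_ORDER[-1]
        idx = int(np.searchsorted(np.asarray(self.edges[1:-1]), score, side="right"))
        return CATEGORY_ORDER[idx]


def categorize(scores: Sequence[float], mode: str = "range") -> Categorizer:
    """Build category bins from all generalized scores of a corpus.

    ``mode="range"``: five equal-width bins over the observed [min, max]
    (top bin closed).  ``mode="quantile"``: bins at the 20/40/60/80th
    percentiles so each holds ~20% of events.  A degenerate corpus with a
    single distinct score yields the "average" label for everything.
    """
    if len(scores) == 0:
        raise ValueError("need at least one score to build categories")
    lo, hi = float(min(scores)), float(max(scores))
    if math.isclose(lo, hi):
        return Categorizer(edges=(), mode=mode)
    if mode == "range":
        edges = tuple(lo + (hi - lo) * k / 5 for k in range(6))
    elif mode == "quantile":
        qs = np.quantile(np.asarray(scores, dtype=float), [0.2, 0.4, 0.6, 0.8])
        edges = (lo, *map(float, qs), hi)
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    return Categorizer(edges=edges, mode=mode)


def rank_events(events: Iterable[EventOccurrence]) -> list[EventOccurrence]:
    """Sort events by normalized confidence, best first; unscored last."""
    return sorted(
        events,
        key=lambda e: (e.norm_score is None, -(e.norm_score or 0.0), e.event_id),
    )
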