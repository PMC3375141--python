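# Methods

`eventpost` post-processes recursive biomolecular events of the kind
produced by shared-task-style event extraction pipelines (nine event
types; Theme/Cause argument roles; arguments that are gene/protein
mentions or, recursively, other events). Its goal is to turn text-bound,
per-sentence extractions into aggregated, ranked gene–gene knowledge:
canonical symbols, family generalizations, confidence scores, flattened
regulatory structures, typed pairwise associations, and shared-partner
hypotheses. This note records the model assumptions, the parameter
choices, and the places where the design was genuinely open.

## Event model and validation

A document carries mentions (0-based, end-exclusive character offsets;
surface must equal the text slice) and events. The argument constraints
are enforced structurally: the five physical types (gene expression,
transcription, localization, protein catabolism, phosphorylation) take
exactly one mention Theme; binding takes one or more mention Themes and no
Cause; the three regulation polarities (positive, negative, unspecified)
take exactly one Theme and at most one Cause, each a mention or an event;
the argument graph must be acyclic. Validation reports violations as data
(rule ids such as `single-theme-type`, `binding-no-cause`,
`regulation-args`) rather than exceptions, so a corpus can be triaged.

Offsets are 0-based and end-exclusive throughout — the standoff
convention — and entity surfaces are compared by code point with no
Unicode normalization ("NF-κB" is kept verbatim; canonicalization handles
stripping). The confidence sidecar (`.conf.tsv`) is this package's own
format, since upstream classifier margins have no standard serialization:
one row per trigger or argument decision. Duplicate sidecar rows are an
error rather than last-wins, because a duplicate almost always indicates
an upstream pipeline bug worth surfacing. We assume one margin per
argument slot; separate per-nested-argument scores are not modelled.

## Canonicalization and generalization

Canonicalization strips affix tokens (whitespace-token based, both ends,
iterated), removes non-alphanumeric characters and lowercases, e.g.
"human Esr-1 subunit" → `esr1`. Decisions taken here:

* The affix lexicon is configuration, seeded with species adjectives and
  structural words ("human", "murine", …, "protein", "gene", "subunit",
  "promoter", "mrna", "homolog"). The procedure matters more than the
  exact list; the list is a YAML file users can extend.
* Non-ASCII letters (Greek) are dropped together with other
  non-alphanumerics, not transliterated ("NF-κB" → `nfb`). Transliteration
  would need a policy table; dropping is deterministic and reversible in
  the sense that canonical keys stay within `[a-z0-9]+`.
* Stripping is token-based, not substring-based, so "protein" inside a
  symbol is never touched. If stripping empties the surface, the rule
  falls back to the lowercased alphanumeric content of the original
  surface; surfaces with no alphanumeric content at all are flagged
  uncanonicalizable and excluded from generalization.
* Canonicalization is idempotent by construction (verified by property
  test over decorated surfaces).

Family schemes are many-to-one tables `canonical symbol → family id`
(HomoloGene-like, Ensembl-like), supplied as TSV. A symbol listed under
several families resolves to the family with the most members in the
table, ties broken by lexicographic family id — the upstream
disambiguation algorithms are out of scope, so a deterministic local rule
is used. A mention's generalization key is its canonical symbol (canonical
scheme) or its family id, falling back to the canonical symbol when
unmapped so that unmapped symbols keep singleton identity rather than
collapsing into one "unmapped" bucket.

## Confidence

Raw SVM margins exist per trigger decision and per argument decision, and
the two classifiers' margins are not mutually comparable. Both kinds are
z-scored over the whole corpus, separately per kind, using the
*population* standard deviation (divide by n) — a corpus-level framing
that keeps the transform deterministic and exactly invertible in tests. A
corpus where either kind has fewer than two distinct values is rejected as
degenerate.

An occurrence's confidence is the minimum of its normalized components
(fuzzy AND: every decision involved must be confident). Events missing
any component score are left unscored and rank last. A generalized
(cross-document) event averages its scored occurrences; unscored
occurrences still count as evidence. Refined events inherit the score of
their original occurrence — the classifiers scored the extraction, not
the rewrite.

Scores are ordinal; no recalibration to probabilities is attempted.

For presentation, aggregated scores map to five labels (very_high … 
very_low). Two readings of "20% per category" exist: 20% of the
confidence *range*, or 20% of *events*. The range reading is the default
(five equal-width bins over the observed [min, max], top bin closed); the
quantile reading is available as `mode="quantile"`. A single-score corpus
has no range to split and degenerates to "average". Bin boundaries are
exported in the run manifest for reproducibility.

## Refinement

The rewrite system removes intermediary single-argument regulatory events
(regulation-class, Theme but no Cause) sitting as the Theme of another
regulation-class event, composing polarities by the nine-rule table in
`eventpost.refine.POLARITY_TABLE` (e.g. Neg∘Neg → Pos, Reg∘Neg → Neg).
Open choices, fixed and documented:

* **Order**: outermost-first, re-scanning from the root after every
  application, with Cause slots visited before Theme slots. Order
  interacts with the one-change budget, so it is frozen and the
  independent test oracle uses the same order.
* **Budget**: at most one genuine polarity change per *root structure*
  (not per chain, not per corpus). Any later type-changing application is
  forced to unspecified regulation. The per-structure reading matches the
  intuition that a single sentence should not license chained sign
  inferences.
* Nested regulations *with* a Cause are never removed — they carry their
  own regulator and are handled by pairwise abstraction instead.
* The original structure is always preserved alongside the refined one,
  with the removed intermediaries (event id and type) kept as provenance.

Termination is immediate (each step removes one event); idempotence, the
fixpoint characterization (unchanged iff no removable nested regulation
exists) and gene-multiset preservation are property-tested on 10,000
random structures.

## Pairwise abstraction

Every unordered pair of distinct gene mentions in one structure is a
candidate, classified at the lowest common ancestor event: binding if
both are direct Themes of one binding event; otherwise a directed
regulation from the Cause-side gene to the Theme-side gene. Two
refinements of that rule:

* A Cause-side gene reached as the *Theme* of a nested event regulates
  only indirectly → `indirect_regulation`. The generalized reading is
  "Theme-descendant on the Cause side": the gene's immediate role is
  Theme. A Cause-of-Cause gene remains a plain regulator.
* A Theme-side gene reached through a nested *Cause* argument cannot be
  convincingly paired with the outer Cause gene; the candidate is
  discarded but kept as a `coregulation_capture` seed (both causes act on
  the inner Theme), which feeds only the coregulation join downstream.

Pairs of genes inside the same argument subtree classify at their own,
deeper LCA. Identical-symbol pairs (self-regulation statements) are never
emitted. Seeds aggregate across documents on (class, key_a, key_b) under
the chosen generalization; binding and capture pairs store keys in
lexicographic order, regulation classes keep orientation, and opposite
directions remain distinct pairs. Aggregate confidence is the mean of
evidence scores; categories come from the corpus-wide range of aggregated
scores. Same-keys/different-class duplicates are kept separate — the
classes group differently in downstream views.

The extractor is verified against a literal step-by-step walker on the
exhaustive enumeration of valid structures with nesting depth ≤ 3 and
≤ 4 genes (988 shapes after deduplication; polarity and physical subtype
do not affect pair classes and are enumerated as single representatives).

## Indirect associations

Aggregated pairs join through shared partners: coregulation (A>Z, B>Z),
common regulator (Z>A, Z>B), common binding partner (A×Z, B×Z).
Indirect-regulation edges participate in both regulatory joins — they
still assert regulation. Capture seeds contribute their stored targets to
the coregulation join only. A shared partner counts once even when
supported by several edge classes. No confidence floor is applied by
default (a `min_score` threshold is available in the pair stage).
Associations are precomputed and exported, ranked by number of shared
partners, then best supporting edge score, then lexicographic keys; every
record carries a `hypothetical` flag — these are literature-derived
hypotheses, and e.g. true coregulation additionally requires coexpression
evidence this data cannot provide.

## Synthetic corpus generator

The generator defines the study conditions for all tests. Each document
holds 3 event structures (a typical abstract yields a handful) drawn from
a mixture over signature patterns whose default weights follow the
prevalence of refined event shapes in large-scale event data: single-gene
physical events dominate (weight 58.6), then bare and physical-nested
regulations (15.0, 8.4), two-gene bindings (8.0), direct regulations
(4.7, 3.8), and three rare nested indirect patterns (0.2 each); weights
are renormalized to 1. Polarities and physical subtypes are sampled
uniformly within a pattern. Removable single-argument regulation chains
(length 1–2) are inserted below regulation-class parents with probability
0.3 so refinement has real work; mention surfaces are decorated with
affixes with probability 0.3 and capitalized at random. Raw margins are
Gaussian per kind (trigger mean 0.8, sd 1.1; argument mean 0.5, sd 0.9 —
arbitrary units; only their normalized form matters). The gene pool is 25
lowercase symbols with partial family coverage (18/25 mapped), so family
generalization and coverage statistics are non-trivial.

Ground truth (canonical symbols, refined structures, pairs, associations)
is computed by intentionally naive, separate implementations bundled with
the generator, so end-to-end tests compare two independent routes. Output
is byte-identical for a fixed seed.

What the generator does *not* emulate: linguistic variation (text is a
deterministic token template), negation/speculation, entity-recognition
errors, cross-sentence or coreference structure, and the heavy-tailed
symbol-frequency distribution of real literature. Passing closure tests
therefore demonstrates correctness of the post-processing algebra on
well-formed inputs, not robustness to noisy upstream extraction.

## Problem sizes and numerics

Default test and acceptance runs use corpora of 40–1000 documents
(120–3000 root events), 10,000 random structures for rewrite-system
properties, and 10,000 decorated surfaces for canonicalization — sizes at
which every check runs in seconds while the binomial sampling error of
mixture frequencies stays within tested bounds. Normalization contracts
are asserted to 1e-10; binning uses half-open bins with a closed top bin,
and label lookup clamps at the observed extremes so floating-point
round-off at bin edges cannot invert the label order. Ties in rankings
are broken lexicographically to keep all exports deterministic.

## Known limitations

* Only the core nine-type event model is supported; sites, coreference
  and other later extensions are out of scope.
* Family mapping quality is entirely inherited from the input tables; the
  ambiguity rule (largest family, lexicographic ties) is a heuristic.
* The pairwise rules cover configurations up to the documented
  generalizations; pathological deeply nested mixtures beyond the
  enumerated space follow the same two descent rules but have no
  independent gold standard.
* Confidence categories depend on the observed score range, so adding
  documents can move category boundaries (by design — they are corpus
  relative).
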