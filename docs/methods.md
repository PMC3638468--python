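# Methods

## Ontology model

Ontologies are directed acyclic multigraphs over CURIE-identified terms with
two interpreted edge types, `is_a` and `part_of`, both pointing child →
parent. The OBO 1.2 reader interprets only `id`, `name`, `synonym`, `is_a`,
`relationship: part_of` and `is_obsolete`; unknown relationship types are
skipped with a logged warning and all other tags silently. Obsolete terms
stay in the graph as flagged nodes — so stale identifiers still resolve —
but their outgoing edges are stripped, which keeps them out of every closure
and out of information-content statistics. A `[Term]` stanza without an `id`
is a parse error naming the line; a cycle over the interpreted edges is a
validation error listing one offending cycle. The writer emits stanzas in
sorted-id order with a fixed tag order, so parse → write → parse is
bit-stable (exercised by the round-trip tests).

Profile closure is reflexive (input ⊆ output), idempotent and monotone, and
takes the relation set as a parameter. The default is `{is_a}` — plain
superclass closure, which is what similarity uses on phenotype graphs.
`{is_a, part_of}` is used for anatomy graphs inside the EQ reasoning, where
partonomy legitimately carries the "affects a part of" abstraction. Ancestor
sets are memoised per (graph, relation-set), making repeated closures over a
corpus linear in practice.

## Cross-species EQ subsumption

A phenotype is decomposed into an affected **entity** (anatomy or process
term) and a **quality** (PATO-style term). Phenotype A subsumes under
phenotype B when

1. A's entity reaches B's entity along is-a/part-of edges, crossing **at
   most one** anatomical homology pair, and
2. B's quality equals A's quality or is one of its is-a ancestors.

One homology hop is a modelling choice, not an optimisation: a homology map
relates exactly two species' anatomies, so chains of hops have no
interpretation here. Homology is symmetric (crossable in either direction);
species-independent entities (processes, functions) are handled by passing
the same graph for both anatomies with an empty homology map. Conflicting or
many-to-many homology assertions are accepted as given and not deduplicated.

`build_bridge` evaluates all definition pairs (A-table × B-table), excluding
self-pairs, and returns axioms oriented A → B only; running it twice with
swapped arguments yields a bidirectional bridge. Oriented axioms installed
into the union of two acyclic phenotype graphs cannot create a cycle, and
`merge_with_bridge` asserts acyclicity after the merge regardless.

## Information content and simGIC

IC is corpus-frequency based: each reference profile is closed, then
`P(x)` counts **profiles** (entities), not raw annotations, and
`I(x) = −log₂ P(x)`. Bits (base 2) are a display choice only — any base
cancels in simGIC's ratio. Terms absent from every closed profile receive
the finite ceiling `−log₂(1/(N+1))`, a pseudo-count that keeps query
profiles with corpus-unseen terms scorable while treating them as maximally
informative. Closure-based counting forces `I(child) ≥ I(parent)` along
every is-a edge (a property test).

simGIC is the IC-weighted Jaccard index over the two closures. Degenerate
0/0 ratios (closures overlapping only in zero-IC terms, e.g. the root) are
defined as 0: such pairs share no information. Summation runs in sorted term
order so the score is exactly symmetric, bit for bit. The pairwise matrix
computes each closure once and orders rows/columns by sorted id, making
output independent of corpus insertion order.

Which corpus defines IC (models, diseases, or both pooled) is left to the
caller; the CLI defaults to pooling queries and targets and accepts an
explicit `--corpus`.

## Ranking and ROC evaluation

Per disease, models are sorted by descending score with ties broken by
ascending model id — fully deterministic. Evaluation pools ranked pairs
across diseases (micro-average): at rank cutoff r,
`TPR(r) = (# positives at rank ≤ r)/(# positives)` and
`FPR(r) = (# negatives at rank ≤ r)/(# negatives)`, where every ranked pair
not in the truth set is a negative. The curve is anchored at (0,0) and
(1,1) and integrated by the trapezoid rule. On this pooled-by-rank curve the
trapezoidal AUC coincides with the Mann–Whitney U statistic on ranks with
ties counted half — the suite certifies agreement to 1e−9 against a
brute-force pairwise oracle. Positive pairs whose model is absent from the
disease's ranking are excluded from both numerator and denominator with a
logged count; diseases without positives still contribute negatives. A
macro-averaged mode (mean of per-disease curves on a merged FPR grid) is
available but not the default, since the pooled curve is the primary
presentation.

The random baseline draws, per replicate, a uniform random truth set and
i.i.d. uniform scores for every pair; with continuous scores ties have
probability zero, so the id tie-break does not bias the AUC. Its mean
calibrates to 0.5.

## Synthetic benchmarks

`generate_ontology(n_terms, max_parents, seed)` grows a single-rooted DAG:
term i > 0 takes 1..max_parents is-a parents uniformly among earlier terms,
acyclic by construction; `max_parents=1` degenerates to a tree. Benchmarks
default to `max_parents=2`, a modest multiple-inheritance rate comparable to
curated phenotype ontologies.

`generate_benchmark` emulates the evaluation setting: disease profiles are
uniform random term sets (the root is never sampled — it carries zero
information), each positive (model, disease) pair's model copies
`ceil(signal × profile_size)` of its disease's terms and fills up randomly,
and negative models are fully random. A model positive for several diseases
copies from each; its profile may then exceed `profile_size`. All randomness
flows through one numpy generator seeded per call — identical specs give
identical benchmarks.

What the generator deliberately does **not** emulate: real HPO/MP term-
frequency skew, correlated annotations within organ systems, annotation
noise and redundancy, or the cross-species bridge (benchmarks use one shared
ontology; the two-ontology + homology path is exercised separately in the EQ
tests). Passing benchmarks therefore demonstrate the correctness and
discriminative behaviour of the machinery under controlled signal, not
field performance on curated resources.

Problem sizes in the tests and the acceptance run — e.g. 300-term graphs,
20 diseases × 100 models, 200 baseline replicates — were chosen as the
smallest scales at which the stochastic properties are stable across seeds;
the whole acceptance computation completes in seconds.

## Lexical mapping

Needleman–Wunsch runs at character level over normalized labels
(lower-cased, punctuation → spaces, whitespace collapsed). Default scoring
is match +1, mismatch −1, gap −1 (linear gaps); the scheme is exposed via
`AlignScoring` since the algorithm choice fixes no parameters. Scores
normalize by `match × max(|a|,|b|)` and clamp to [0,1], so self-similarity
is exactly 1 and, under match > mismatch and gap < 0, normalized 1 holds iff
the strings are equal. Aligning two empty strings is an error; one empty
side is allowed and scores all-gaps.

Term candidates are the label plus EXACT and NARROW synonyms; BROAD and
RELATED synonyms are excluded by default to avoid over-broad equivalence
assertions. The default acceptance threshold is 0.85 normalized similarity —
strict enough that accepted matches are near-verbatim, while tolerating
small orthographic variation; it is a tunable, not a calibrated constant.
Signs without an accepted direct match are promoted structurally: ancestors
are walked breadth-first (nearest level first, within a level in parent-list
order), and the first ancestor with an accepted match yields a SUBCLASS_OF
assertion to that ancestor's matched term. Token-level alignment and any
manual-curation workflow are out of scope.

## Numerical and degenerate-input conventions

- All scores and rates are IEEE doubles; no tolerance is applied internally.
  Test tolerances: 1e−9 for AUC-vs-U-statistic, 1e−12 for simGIC vs its
  set-enumeration oracle, exact equality elsewhere.
- Ties: ranking ties break by ascending id; the U-statistic counts rank ties
  half — with continuous scores the two conventions coincide almost surely.
- Empty profiles are rejected at similarity time; empty corpora, truth sets
  without a positive (or without a negative), inconsistent benchmark specs
  and cyclic hierarchies all raise typed errors rather than degrading.
- CLI exit codes: 0 success, 1 data/validation errors, 2 usage errors.
  Outputs are written atomically (temp file + rename) with `#`-prefixed
  provenance headers; matrices use fixed 6-decimal formatting so reruns are
  byte-identical.

## Known limitations

- The EQ reasoner is a graph-reachability approximation of description-logic
  reasoning: no qualifier fields ("towards" entities), no relational
  qualities, no equivalence-class inference.
- simGIC is the only similarity measure; Resnik/Lin/best-match-average are
  not provided.
- The OBO dialect is deliberately narrow (no cross-products, no OWL).
- Lexical mapping has no notion of word order or tokens; long labels with
  permuted words score poorly at character level.
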