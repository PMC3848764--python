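# Methods

## Data model

A study is a set of patients, each observed over the same ordered, numeric
timepoints. Timestamps are taken from the column labels themselves (days,
weeks, or plain indices), never from positional rank, so non-uniform
sampling keeps its true gaps and the window/gap parameters below are in the
study's own time units.

Discretization divides every reading by the patient's baseline reading of
the same gene (the earliest timepoint by default; selectable, since some
designs start treatment at day 0). The signed fold change is the ratio
when ≥ 1 and the negated reciprocal otherwise, so its magnitude is always
≥ 1 and the baseline maps to exactly +1. A gene becomes an up (down) item
at a timepoint when its unrounded signed fold change is `>= t`
(`<= -t`) for the fold threshold `t > 1`. "Meets the threshold" is
implemented as a weak inequality: the toy fixtures contain a boundary cell
(|sfc| = 1.5015 at threshold 1.5) that must be emitted, and the weak rule
is the one under which every printed cell of the worked example is
reproduced. Missing cells simply produce no item; no imputation,
normalization or probe collapsing is attempted — inputs are assumed
preprocessed.

Two pre-mining filters remove housekeeping-like items: an explicit gene
list, and the minTSupp rule, which removes an item recurring in at least
`ceil(minTSupp * T_p)` of a patient's `T_p` transactions. minTSupp is
judged **per patient** by default — "recurs at most timepoints" is read as
a property of one patient's own time course — with a pooled-across-patients
variant behind a `scope` switch, since either reading is defensible.
Filters drop emptied transactions and patients, but the support denominator
stays at the original patient count: supports remain "out of all patients",
which is also why `SequenceDB` carries an explicit `n_total`.

## Mining semantics

A pattern is an ordered list of elements; an element is an ordered list of
signed items in temporal order. The miner is a depth-first
prefix-projection search:

* **Projection.** For each patient, the projected database stores the
  postfix starting right after the *first admissible occurrence* of the
  prefix, together with the anchor timestamp of the current element.
* **Extension classes.** Scanning a postfix, each item's *first*
  occurrence is classified by its gap `g` from the anchor: an itemset
  extension (merged into the current element) when `0 < g <= SWS`, a
  sequence extension (new element) when `SWS < g <= maxTC`, ignored when
  `g > maxTC`. An occurrence inside the window is *only* an itemset
  extension; it is never double-counted as a sequence extension, and later
  occurrences of the same item are not consulted. These two rules are what
  make the constrained worked examples come out exactly as printed: with a
  1-unit window the toy database yields `<(G1+G3+)>` but *not*
  `<(G1+)(G3+)>`, because every first occurrence of `G3+` falls inside the
  window.
* **Anchors.** The element anchor defaults to the element's *first* item
  (element span ≤ SWS), the common windowed-sequential-pattern convention.
  The single-step printed examples cannot distinguish first- from last-item
  anchoring, so the alternative is available as
  `MiningParams(window_anchor="last")`.
* **Cross-timepoint restriction.** Projection always starts at the
  transaction *after* the prefix occurrence, so two items of one
  transaction never join a pattern directly — co-occurrence elements arise
  only through the window. The bundled `traditional_mine` drops exactly
  this restriction (elements are same-transaction itemsets) to show the
  redundant patterns the restriction removes.

Supports count distinct patient sequences; the threshold is
`ceil(minSupp * n)`, computed as `ceil(x - 1e-9)` to keep binary floating
point from turning e.g. 95% of 20 into 20 instead of 19. The miner is
fully deterministic: candidates are explored in canonical item order (gene
lexicographic, `+` before `-`) and output is sorted by length then
serialization.

**Completeness.** With `SWS = 0` and unbounded `maxTC`, first-occurrence
projection is complete and agrees exactly, supports included, with the
declarative semantics ("is there *any* embedding?") implemented by
`pattern_support` and the brute-force oracle — a property the test suite
checks on hundreds of randomized databases. Under a finite `maxTC` or an
open window it can miss embeddings anchored at later occurrences, so the
mined set is then a guaranteed *subset* of the declarative one (also
tested). This one-pass greedy behaviour is treated as part of the method's
definition, not a bug: every reported pattern is witnessed by real
embeddings (soundness), downward closure holds, raising `minSupp` never
adds patterns, and relaxing `maxTC` never removes any.

`pattern_support`'s embedding definition: items of one element come from
strictly increasing distinct transactions within the window of the element
anchor; consecutive elements' anchors differ by more than `SWS` and at most
`maxTC`.

## Reports and enrichment

The characteristics summary counts patterns, the maximal pattern length,
the patterns reaching it, and the distinct genes and ordered gene pairs in
the longest patterns (only those with ≥ 2 items; a run whose maximum is
length-1 reports zeros there, and length-1 patterns count as patterns by
default). "Gene pairs" is not a standardized quantity; the default counts
distinct ordered (earlier, later) gene pairs over all item pairs with
strict positional precedence, directions ignored and repeats like (G3, G3)
allowed. Direction-aware and consecutive-only counting are selectable —
the definition is isolated in one function precisely because it is a
judgement call.

Parameter sweeps re-mine per grid value varying exactly one of `minSupp`,
`minTSupp`, `SWS`, `maxTC`, the practical order in which defaults are
tuned (the parameters are examined from the most to the least
output-shaping).

Enrichment is a flat upper-tail hypergeometric test: for a query of size
`N` from a universe of size `M` and a set of size `K` (intersected with
the universe), `p = P(X >= k)` via `scipy.stats.hypergeom.sf(k-1, M, K, N)`.
Reported as `-log10(p)`; log base is a convention choice and is labelled.
No correction by default (single-set usage); Benjamini–Hochberg is a
switch. Ontology handling (DAG, term propagation) is deliberately out of
scope — user-supplied GMT sets stand in for GO categories, so absolute
enrichment scores are not comparable to tools that propagate terms.

## Synthetic cohorts

The generator emulates the *shape* of clinical time-course cohorts — by
default 11 patients over 10 unit-spaced timepoints with 30 genes, matching
the scale of a small inflammation cohort. Planted chains are ordered
(gene, direction, lag) cascades; each patient carries a chain with
probability `penetrance` (default 0.9), and a carried event sets the cell
to the patient's own baseline reading × `fold_magnitude` (default 4, i.e.
more than twice a 1.5–2 discretization threshold) or its reciprocal, so
the planted signed fold change equals ±`fold_magnitude` exactly.
Everything else is the baseline level (default 100) times lognormal jitter
(σ = 0.05, ~5.7σ below a 1.5 threshold), plus spurious threshold-crossing
"noise events" at `noise_event_rate` per non-baseline cell (default 1%,
direction uniform). All randomness flows from one integer seed through a
single generator, so same-seed runs are byte-identical.

What passing tests show: the pipeline recovers planted cascades perfectly
when penetrance exceeds the support requirement with margin and noise is
rare, and on pure-noise cohorts mined pair supports stay within a loose
Bonferroni binomial bound derived from the closed-form per-patient pair
probability. What they do not show: behaviour under probe-level
artifacts, correlated noise, normalization effects or real cohort
structure — the generator deliberately models none of these.

## Problem sizes and runtime

All worked-example checks run on the bundled toys (3–4 patients). The
randomized oracle comparison uses 200 databases of ≤ 5 sequences, ≤ 6
timepoints and 5 genes — small enough that the exhaustive oracle
enumerates every embedding — and the synthetic recovery/noise checks use
20 seeded replicates of the default 11 × 30 × 10 cohort. The full suite
runs in a few seconds on one CPU.

## Known limitations

* First-occurrence projection is incomplete under finite constraints (see
  above); the declarative oracle bounds the loss but cannot be run at
  scale.
* Gene symbols containing `( ) + - < >` or whitespace are rejected rather
  than escaped; rename such identifiers upstream.
* `minTSupp`'s pooled variant and the `last` window anchor are provided for
  sensitivity analysis; defaults follow the readings argued above.
* The traditional miner is an exhaustive-growth reference for small
  databases, not a performant GSP/PrefixSpan reimplementation; it exists
  for comparison, and both reference miners guard against large inputs.
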