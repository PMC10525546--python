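# Methods

## The statistic

The package operationalises social cohesion over a 7-day window of
DR-annotated text. The annotation unit is one DR instance: a single text
occurrence can contribute zero, one or several units, so weekly totals
count repertoires, not texts. Given per-DR counts, each of the two
cohesion dimensions — *anticipation of future scenarios* (x) and *shared
management* (y) — is summarised by its frequency-weighted mean dialogic
weight; weights are fixed constants of the taxonomy (0–20 scale), not
estimated from data. The assumptions are therefore: (i) the weight table
is exogenous and constant over time; (ii) annotation units are
exchangeable within a week; (iii) the two dimensions are commensurable on
the same 0–20 scale.

### Aggregation strategies

The published material defines the two variables, the weights, the 0–20
index range and one worked output, but not the rule combining the two
variable means; that rule lives in an unpublished companion formalisation.
The package therefore treats aggregation as a pluggable strategy recorded
in every result:

- **`xy-mean`** (default): the arithmetic mean of the two variable means —
  the simplest rule consistent with a two-dimensional operationalisation
  and the 0–20 range. On the worked-example week it gives 10.6816 → 10.68
  (2 dp) against the reported 10.76; the 0.08 residual is a known gap and
  is asserted as such (|computed − reported| ≤ 0.15), never calibrated
  away.
- **`pooled-mean`**: the overall frequency-weighted mean across both
  variables (9.92 on the same week), kept as a transparency baseline.

A variable with zero mass is reported as *undefined*, never imputed as 0
(which would crater the index); the default strategy then returns the
defined mean and flags the result `single_variable`.

### Reporting precision

Shares and indices are computed at full float precision and rounded
half-up to 2 decimals only at the reporting boundary
(`round_half_up`, `decimal`-based). Week-over-week deltas below 0.005 —
half a reporting unit — are labelled "stable".

## Corpus handling

- **Selection criteria** are applied in the order time → content → author
  → geography, and each excluded record is tallied against the first
  criterion it fails. Content matching is case-insensitive substring after
  whitespace normalisation against the 8 shipped Italian topic queries (or
  user keywords); this is the simplest reproducible reading of
  keyword-based retrieval. Filtering is order-preserving and idempotent.
- **Quota sampling** apportions a target across the five source classes
  (Facebook 25%, Twitter 10%, Instagram 10%, national/regional news 30%,
  local news 25%) by the largest-remainder method with alphabetical
  tie-break — deterministic and seed-independent — then samples uniformly
  without replacement within each source from a single seeded generator.
  Undersupplied sources contribute everything they have and the shortfall
  is reported, never silently rebalanced.
- The two daily pool quotas (2,500 social media, 5,000 news) are read as
  *pooled* quotas per day; over a 7-day window they give the design total
  of 52,500 occurrences/week, which is the only reading consistent with
  that printed total.
- The **keyword helper** ranks lowercased tokens by raw frequency
  (alphabetical tie-break) and returns an empty `relevant` column: the
  final keyword choice is an expert judgement and is deliberately not
  automated.

## Taxonomy

The registry ships the 23 published (name, variable, dW) triples — 9 x,
14 y — plus aliases for the spelling variants used in published frequency
tables. The taxonomy nominally counts 24 repertoires but only 23 weights
are published; rather than invent a weight, the registry supports user
extension (`with_entry`). DR typology (generative / stabilization /
hybrid) is carried as metadata only and defaults to `unknown`: the full
typology mapping is unpublished, and no published rule makes typology
modify a weight.

## Annotation baseline

Expert DR coding is skilled human work (with a machine-learning
counterpart under development elsewhere); neither can ship here. The
bundled `LexiconClassifier` is a deterministic cue-word → DR rule table
applied per sentence — a transparent stand-in that makes the pipeline
runnable end to end. Its labels are registry-checked (an unregistered
label is a hard error) and its accuracy relative to expert coding is
**not** claimed or measured. Raw labels are stored alongside their
canonical resolution so alias mapping stays auditable.

## Synthetic-data generator

`generate_corpus` draws DR labels i.i.d. from a configurable multinomial
whose default is the worked-example week's empirical distribution
(n = 1,323); dates are uniform over the window (no intra-week distribution
is published); sources follow the retrieval-design shares; the author mix
is citizen-dominated (80% citizens, 10% journalists, 10% institutional and
health roles — a realistic reading of comment-heavy retrieval, chosen once);
provinces are uniform over the 7 Veneto provinces. Placeholder texts embed
one of the 8 topic keywords so generated corpora pass content filtering by
construction.

What the generator does **not** emulate: real linguistic content,
per-source label dependence, intra-week news cycles, duplicated
cross-posts, or annotator disagreement. Passing tests therefore
demonstrate correctness of the *computation* under the stated statistical
structure, not robustness to real-data messiness.

### Corpora at target index values

`generate_trend` must produce weeks whose expected default index equals a
requested target t. A mixture of one x-DR and one y-DR cannot do this:
whenever both variables carry mass, each variable mean equals its single
DR's weight, so the xy-mean index is constant regardless of the mixing
proportion. Instead, for each variable whose weight range contains t, the
generator mixes the two *adjacent* registry weights bracketing t with
probabilities solved from p·w_hi + (1−p)·w_lo = t; mass is split evenly
across the feasible variables. Each variable's per-draw mean is exactly t,
so the expected index is exactly t; choosing the narrowest bracket also
minimises sampling variance (worst case, targets inside the 12.18–19.14
gap of the x scale, has per-draw SD ≈ 3.4, i.e. an index SE ≈ 0.03 at
n = 5,000). Targets in [0.87, 1.74) or (18.27, 20] are attainable by one
variable only and yield flagged single-variable weeks; targets outside
[0.87, 20] are rejected.

## Problem sizes and seeds

All randomness flows through integer seeds into `numpy` generators; fixed
seed ⇒ byte-identical corpora, samples and rendered reports. The recovery
experiment uses targets {5, 10, 15}, n = 5,000 units/week and 100
replicates per target — large enough that the ±0.2 recovery band is a
many-sigma event, small enough to run in seconds on one CPU. Property
sweeps use 1,000 random tabulations with totals ≤ 10,000 and check the
means against a brute-force sum-product oracle at 1e-9.

## Known limitations

- The exact published aggregation rule (yielding 10.76 on the worked
  example) is unavailable; the default strategy reproduces it only to
  within 0.08. Plug in a custom strategy via `register_strategy` if the
  rule becomes available.
- The published narrative split of one week's data into 67.83% / 32.17%
  groupings rests on an unpublished partition of the DR table and is not
  reproduced.
- Historical trend figures exist only as a plot in the source material;
  trend functionality is validated against synthetic targets instead.
- The lexicon baseline is illustrative; substantive use requires expert or
  model annotation plugged into the `Classifier` seam.
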