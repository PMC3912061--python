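# Methods

## Model and assumptions

`chemrank` ranks indication categories for a query compound by a one-hop
weighted vote over a chemical–chemical interaction network:
score_k(q) = Σ_{d≠q} Q(q,d)·y_{d,k}, where Q is the pairwise confidence
score and y the training drugs' binary label matrix. The operating
assumption is label homophily: interactive compounds (positive combined
score) are more likely to share indications than non-interactive ones. The
model has no fitted parameters; all information flows through the network
and the training labels, which is why leave-one-out evaluation reduces to
excluding the held-out drug's own label row (and any self-edge) from the
vote.

Two compounds are treated as interactive iff their chosen channel score is
strictly positive; absent pairs score exactly 0 and are never stored.
Scores are used raw: the ranking is invariant to multiplying all scores by a
positive constant, so normalising the 0–1000 database scale would change
reported score values but no prediction.

The descriptor comparator replaces Q(q,d) with the cosine similarity of
fixed-dimension molecular-descriptor vectors. Negative cosines are summed
as-is — the vote formula has no clipping, and negative structural evidence
legitimately pushes a category down the ranking. Descriptors are not
standardised by default (the comparator mirrors the literal formula); a
zero-norm vector gets similarity 0 (neutral) with a warning, since the angle
is undefined.

## Ranking conventions

Rankings are full length: all M categories appear, with the zero-score tail
included, because the evaluation framework inspects all M orders and the
coverage identity r(M) = 1 only holds for full rankings. Equal scores are
broken by ascending catalogue position — the catalogue order fixed at
construction is the single source of tie policy — and tie groups are
recorded on every prediction so any alternative policy can be audited. An
optional truncate-zero mode drops the zero tail for presentation.

## Evaluation statistics

* j-th order accuracy Q_j = (drugs whose j-th ranked category is true)/N.
* Per-category order accuracy A[i,k] over the N_k drugs carrying category k;
  when N_k = 0 the quantity is undefined and reported as NA, never 0 — a
  printed 0.00% always means a genuine zero count over a non-empty
  denominator.
* Coverage r(m) = Σᵢ|top-m ∩ trueᵢ| / Σᵢ nᵢ, with the depth
  m = ⌈(Σᵢnᵢ)/N⌉ by default (the smallest integer no less than the average
  number of indications per drug).
* Set precision/recall are per-drug averages; an empty predicted set
  contributes 0 to precision and is logged. With singleton first-order sets,
  precision coincides with Q₁ exactly.
* Held-out (validation/independent) queries are scored against the full
  training set with no leave-one-out. Drugs absent from the network evaluate
  as all-tied catalogue-order rankings by default; `--drop-isolated`
  discards them instead, reproducing the common curation choice of excluding
  compounds without interaction data.

Metrics are computed in full precision; the TSV report prints two-decimal
percentages. Uniform-guess expected rates are reported in two conventions:
full precision (Σnᵢ/N)/M, and a rounded-intermediate variant that divides
the two-decimal average by M — published worked examples mix the two (e.g.
1.31/8 → 16.38% but 34/72 → 47.22%), so both are available and the
acceptance script emits the variant conventionally quoted for each split.

## Null controls

Random label transfer copies the true label set of one uniformly drawn
*other* drug (jackknife style); with singleton labels everywhere its
expected precision equals its expected recall. The score permutation
reassigns the confidence scores to edges by a uniform permutation over all
edges — the strongest parameter-free reading of "exchanging the scores of
some interactions" — conserving the edge set and the score multiset exactly;
a `fraction` option permutes a random subset for sensitivity analysis. All
randomness flows from one seed (NumPy `default_rng`); callers needing
independent substreams pass a shared `Generator`.

## Synthetic data generator

The generator emulates a small curated oncology benchmark: n drugs each get
a primary category from a weight vector (default: the 8-category marginal
(9,13,30,19,10,14,7,9)/111 of a 68-drug benchmark) and a second distinct
category with probability 18/68; an exact-count mode deals category slots
without replacement so per-category column sums hit requested marginals
exactly (extras go to drugs with the fewest labels, keeping the multi-label
drug count minimal as in curated tables). Edges are independent Bernoulli
draws at p_within for same-label pairs and p_between otherwise (defaults
0.35/0.15, chosen once to give overall density near the ~0.22 of a
1,393-edge network over 112 compounds with moderate homophily); scores are
uniform integers on [150, 999], reflecting a 0–1000 confidence scale.

Two distinct homophily channels matter for the null experiments:

* **edge-presence homophily** (p_within > p_between) — what the jackknife
  recovers; invisible to a score permutation, because permuting i.i.d.
  scores leaves the network distributionally unchanged.
* **score-carried homophily** (`within_score_low/high` set, same-label edges
  drawing from an elevated range) — what the score permutation destroys.
  The permutation-collapse experiment therefore uses p_within = p_between
  with within-edge scores on [600, 999] against [150, 450] elsewhere; this
  is the regime in which a permutation null can (and does) collapse Q₁ by
  well over half.

Descriptors: each category gets a mean vector drawn N(0, effect²·I_D); a
drug's vector is the mean of its categories' means plus N(0, I_D) noise, so
the expected within-category cosine is ≈ effect²/(1+effect²) (default
effect = 1.0 → ≈ 0.5, comfortably above the ≈ 0 between-category cosine).

What the generator does **not** emulate: real descriptor correlation
structure, degree heterogeneity and hub compounds, channel-specific score
provenance (text-mining vs experimental), and identifier-mapping noise.
Passing tests on synthetic data therefore demonstrate correctness of the
algorithms and the qualitative signal/null behaviour, not the accuracy
attainable on any real interaction database.

## Numerical and design choices

* Duplicate unordered pairs in an interaction file keep the maximum score
  (deterministic and conservative), with a warning; self-edges are dropped.
* Compound identifiers are taken verbatim; an optional two-column id-mapping
  table translates database ids to label-table codes — no prefix logic is
  baked in.
* Catalogues allow M ≥ 1 (a single-category catalogue makes the uniform
  guess trivially perfect, a useful degenerate check); the prediction
  problem is only interesting for M ≥ 2.
* Label files parse in long or wide form, auto-detected: wide iff every
  data cell after the id column is a 0/1 indicator.
* Brute-force cross-checks in the test suite use ≤ 12 drugs and M ≤ 8;
  recovery/null/permutation experiments use 200 drugs, 20 seeds and 50
  permutations — sizes at which the Monte-Carlo standard errors are a few
  percent and a full run of suite plus acceptance script stays under a
  minute.

## Known limitations

One-hop voting only: no network propagation, no weighting of the four
sub-channel scores, no calibration of scores to probabilities. Cold-start
compounds (no interactions) receive the uninformative all-tied ranking.
Reproducing published accuracies on a specific interaction-database snapshot
additionally requires that snapshot and the id mapping used to curate it,
which are inputs, not part of this package.
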