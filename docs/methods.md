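# Methods

## The screening model

A simulated run reproduces the default pipeline of active-learning
screening tools: records are represented as TF-IDF vectors and ranked by a
multinomial naive Bayes classifier retrained after every labeling
decision, with certainty-based selection (always reveal the record with
the highest predicted relevance).

Featurization is deliberately minimal and frozen, because TF-IDF dialects
differ across implementations and any drift makes trajectories
irreproducible:

* text = `title + " " + abstract`, lowercased;
* tokens = matches of `(?u)\b\w\w+\b` (word characters, length ≥ 2);
* weight = `tf · (ln((1+N)/(1+df)) + 1)`, then per-record L2
  normalization;
* the vocabulary is fit once on the full corpus.  Labels never enter
  featurization, and the ranking interface receives no labels of
  unrevealed records, so the oracle cannot leak into the ranker.

Records whose title and abstract are both empty are kept (dropping them
would change `N` and every percentage statistic) but flagged and always
ranked last.

Tunables, all surfaced in the run configuration:

| parameter | default | meaning |
|---|---|---|
| `f` | 0.01–0.30 grid | prior-sample fraction of `N`; sample size `n_s = max(2, round_half_up(f·N))` |
| `alpha` | 1.0 | additive smoothing of the naive Bayes model |
| `retrain_every` | 1 | reveals between retrains; small batches (≤5) do not change results on separable corpora and speed large runs |
| `prior_policy` | `resample` | see below |
| `criterion2_scope` | `active-only` | see below |

## Prior-sample degeneracy

At small `f` and low prevalence a uniform prior sample often contains no
relevant record, and no classifier can be trained.  The default policy
redraws the sample with an incremented sub-seed (bounded at 1000 attempts,
count recorded on the sample) — this guarantees a trainable prior but
biases `r_s` upward at tiny `f`, which is why the estimator-unbiasedness
test runs under the alternative `accept-degenerate` policy, which keeps
the first draw regardless.  Under that policy the criterion-1 estimate can
legitimately be 0; `apply_criterion1` with `R̂ = 0` fires immediately at
position 0, and the screening loop consumes records in corpus order until
both classes have been seen.

## Stop rules: frozen conventions

* **Counting**: `stop_index` always counts all screened records, prior
  phase included — those records were manually reviewed.  The same applies
  to all percentage statistics (`pct_to_last_relevant`, `g_pct`,
  criterion-3 cutoffs `⌈p·N⌉`).
* **Criterion-2 scope**: streak counting defaults to starting after the
  prior phase (`active-only`), because irrelevant runs inside a *random*
  prior say nothing about the ranker; `full` mode is available for
  sensitivity analysis and can fire before any relevant is seen.
* **Minimal safe streak** `g`: the largest run of consecutive irrelevants
  strictly *between* two relevants; runs before the first and after the
  last relevant are excluded.  The off-by-one is resolved explicitly: `g`
  is the largest gap survived, `g+1` is the provably safe threshold, and
  both are reported.  The `g+1` safety guarantee presumes streak counting
  cannot fire before the first relevant — true under `active-only` scope
  whenever the prior holds at least one relevant, which the `resample`
  policy ensures.
* **Criterion-1 error**: `(R̂ − R)/R · 100`, normalized by the true `R`
  (positive = overestimate); the estimator uses half-up rounding, as do
  all printed one-decimal percentages.
* **Outcome categories**: `overestimate` (`R̂ > R`, rule never fires),
  `exact`, `miss_one` (`R̂ = R−1`), `miss_many` (`R̂ < R−1`).
* **Aggregation**: sample SD (`n−1`); the pooled "Total" row of the
  criterion-1 error table pools all runs rather than averaging cell means
  (switchable, since either reading of a grand total is defensible).

## The synthetic-corpus generator

Bag-of-words multinomial mixture over a vocabulary of `V` terms (default
500), of which the first `max(2, V/10)` form a reserved topic block:

* irrelevant records: Zipf-weighted distribution over the non-topic terms;
* relevant records: `δ·Uniform(topic) + (1−δ)·background`; `δ = 0` makes
  the classes indistinguishable, `δ = 1` gives disjoint vocabularies;
* `⌊hard_fraction·R⌋` relevants are drawn from the background instead
  (default `hard_fraction = 0.1`) — relevants no term-frequency ranker can
  find early.  These reproduce the qualitative pattern seen in real
  benchmarks, where some runs must screen almost the whole corpus to find
  the last relevant record;
* record length ~ Poisson(`doc_length`, default 60), minimum 3 tokens; the
  title holds the first 5 tokens so the title+abstract concatenation path
  is exercised.

What the generator does *not* emulate: natural language (word order,
synonymy, topic drift), duplicate records, metadata fields beyond
title/abstract, and label noise.  Passing tests therefore demonstrate the
*mechanics* of the pipeline and the exact semantics of the stop rules —
not that any particular threshold is safe on real reviews.

## Grid design and reproducibility

The study design is `|datasets| × |prior fractions| × replicates`
independently seeded runs; the reference design uses 7 fractions
(1–30%) × 1000 replicates, i.e. 7,000 runs per dataset.  The seed of
replicate `k` of fraction `j` of dataset `i` is
`SeedSequence(base_seed, spawn_key=(i,j,k))`, so any cell can be recomputed
in isolation and interrupted runs resume from complete cells.  Identical
configurations produce byte-identical aggregate files.

Problem sizes in the shipped demo grid and test suite are scaled down —
synthetic corpora of a few hundred records, 20 replicates, 3 fractions —
chosen so the whole pipeline (including per-decision retraining) runs in
minutes while preserving the phenomena of interest: the demo pairs a very
rare class (0.6%, which at the default `hard_fraction` has no hard
relevants) with a common one (6%, three hard relevants), spanning the
prevalence range of real screening benchmarks.  The full-scale design
remains pure configuration.

## Known limitations

* Only the naive-Bayes/TF-IDF pipeline is implemented; other rankers
  (SVM, logistic regression, embeddings) may order records differently.
* Statistically guaranteed-recall stopping rules (e.g. hypergeometric
  confidence bounds) are out of scope here and a natural extension.
* The criterion-1 estimator inherits the resampling bias described above
  at very small prior fractions; results at `f = 1%` on low-prevalence
  corpora should be read with that in mind.
* Single-reviewer oracle labels: no human error model, no dual screening.
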