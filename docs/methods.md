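# Methods

This note records the model, the numerical choices, and the design decisions
behind `adindex`, in the spirit of a statistical software methods appendix.

## Model and procedure

The package treats daily discussion of air quality as a noisy linear sensor
of ambient PM₂.₅. For a fixed city, let *f*(term, *t*) be the fraction of
day-*t* posts containing a character n-gram ("term"), and *P_t* the daily
mean PM₂.₅ (µg/m³, mean of hourly readings over hours 00–23).

**Per-term model.** Each candidate term is scored through
*P_t* = α₀ + α₁ *f*(term, *t*) + ε under four-fold *blocked* cross-validation:
the aligned days are cut into four contiguous, near-equal sections (remainder
days going to the earliest sections); for each section the model is fitted on
the complementary days and the section's score is the Pearson correlation
between its held-out estimates and observations. The term score is the mean
of the four section correlations; the sign is sign(α₁) from the all-days fit.
Blocked (chronological) rather than shuffled folds respect the strong
autocorrelation of pollution time series; a shuffled-fold option exists for
sensitivity analysis. Note the score is a prediction-vs-observation
correlation, so it is non-negative in expectation for informative terms of
*either* sign; direction lives entirely in the sign attribute.

**Index.** Term frequencies span orders of magnitude, so each selected
term's fraction vector is standardized (population convention: divide by
√(mean squared deviation)) before aggregation:
ADI*_t* = Σ sign(term)·z(*f*(term, *t*)). An exactly constant fraction
vector is flagged degenerate and contributes zero rather than NaN.
Constancy is detected by exact equality of the vector's elements, not by
`sd == 0`: round-off in the mean can leave a ~1e−17 spurious sd whose
division would fabricate large z-values.

**Selection.** Candidate terms (those appearing on average ≥ once per day;
the boundary is inclusive, configurable to strict) are ranked by score into
the Sorted Term List. The Final Term Set is grown greedily: scanning the top
*N* = 500 entries in rank order, a term is kept iff the blocked-CV evaluation
score of the index *strictly* increases over the best score so far
(initialized at 0, the defined score of an empty set). The acceptance trace
is therefore monotone non-decreasing by construction.

**Final model.** PM is regressed on the ADI over the learning period only
(closed-form OLS) and applied to the held-out validation period. Negative
PM estimates are physically impossible but are *retained* and flagged —
clipping would silently distort the correlation diagnostics; a
clip-nonnegative option exists for presentation.

## Leakage policy

The published construction z-scores each term over *all* days and thresholds
candidates over the whole dataset. By default this package computes candidate
counts and standardization statistics on the **learning period only** and
applies them unchanged to validation days, so no validation information
enters selection or scaling; `normalization="paper-exact"` restores the
all-days construction. Per-term scoring, selection and the final fit always
use learning days only; validation days are touched exactly once, by the
frozen model.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n` | 2 | character-window length; 3 supported (costlier, rarely better) |
| `dedup_scope` | day | collapse identical posts per (city, day); `global` available |
| `min_hours` | 18 | hourly coverage (75%) required for a daily mean |
| `top_n` | 500 | STL prefix scanned by the greedy selection |
| `folds` | 4 | sections in the blocked cross-validation |
| `threshold_strict` | False | once-per-day candidate boundary: ≥ (default) vs > |
| `normalization` | learning | statistics window (see leakage policy) |

Timestamps are taken at face value: post and monitor clocks are assumed to
share a timezone. MD5 is used purely as a content-equality key (no security
claim). Text canonicalization before hashing is NFC normalization plus
trailing-whitespace stripping only — no case folding or punctuation removal,
since windows operate on raw characters. Windows break at whitespace only;
whether punctuation should also break them is a known open choice, and
punctuation characters are retained as ordinary window content.

## Synthetic corpus generator

The generator emulates the statistical shape the method assumes, not real
language:

- **PM series**: lognormal AR(1), log *P_t* = µ + φ(log *P_{t−1}* − µ) + ε,
  with µ = 4.44, stationary sd 0.5, φ = 0.7 (mean ≈ 100 µg/m³), and extreme
  days (probability 0.035) multiplied by 2.5 — a heavy-tailed, autocorrelated
  series with occasional severe-pollution days.
- **Coupling**: a signal term of sign *s* enters each post with probability
  clamp(*b*·(1 + 0.8·*s*·*z_t*), 0, 1), where *z_t* standardizes the
  concentration series itself (level scale). Level-scale coupling makes
  discussion respond hardest to the extreme days, consistent with how severe
  episodes dominate public reaction, and makes the per-term linear model
  correctly specified.
- **Base rate** *b* = 0.002: a given common term appears in ~1 in 500 posts
  (~4 posts/day at the default 2000 posts/day — comfortably above the
  once-per-day candidate threshold, far below saturation). Posts are
  concatenations of the sampled two-character terms *without* separators, so
  bigram extraction must recover the planted terms amid spurious boundary
  bigrams, each individually too rare to pass the candidate threshold; a
  separator mode yields whitespace-delimited terms for clean unit tests.
  Every character is unique to one vocabulary term, so boundary bigrams never
  collide with planted ones. Posts that draw no terms at all are dropped.
- **Duplicates**: each post is, with probability 0.10, replaced by a copy of
  another same-day post — the same-day scope matching the dedup default.
- Defaults: 400 days, Poisson(2000) posts/day, 2000 noise terms, 20 positive
  + 20 negative signal terms, coupling 0.8. All randomness flows from one
  integer seed; corpora are bit-reproducible.

What passing recovery tests shows: the pipeline finds planted monotone
couplings under realistic counting noise, duplication, and tokenizer stress.
What it does not show: robustness to seasonality confounders shared by terms
and PM, topic drift, near-duplicate posts (only exact duplicates are
modelled or removed), or real linguistic structure.

## Problem sizes in tests

The test suite runs the full default study (400 days × ~2000 posts/day)
across 20 seeds for parameter recovery; null-calibration uses 120–260-day
corpora with a few hundred posts/day, enough for ≥1000 candidate terms and a
~60-day validation window; the dedup-rate check uses a ~40 000-post corpus at
the default vocabulary composition, where the ±5% band around the planted
10% duplicate rate spans more than three binomial standard deviations.

## Numerical and degenerate-input conventions

- Pearson correlation of any constant vector is defined as 0 (not NaN), so
  degenerate folds and sections penalize rather than crash; OLS on a constant
  predictor returns slope 0, intercept mean(y), flagged degenerate.
- STL ties break lexicographically on the term; all orderings are
  bit-reproducible given identical inputs.
- A term whose slope is exactly 0 gets sign +1 (the case has probability
  zero on real data; a fixed convention keeps runs deterministic).
- Section boundaries, fold geometry and the resolved configuration are
  logged/exported with every run for provenance.

## Known limitations

- Exact-duplicate removal only; retweet-marker or suffix-padded
  near-duplicates pass through.
- No multiple-testing correction on term scores; the held-out validation
  period is the guard against selection bias, as in the original design.
- Single-city models only; no pooling across cities.
- Greedy selection is order-dependent by construction: a term rejected early
  is never reconsidered, and no regularized alternative (e.g. lasso) is in
  scope.
- Daily resolution throughout; sub-daily dynamics are averaged away.
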