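# adindex — nowcasting daily PM₂.₅ from social-media term frequencies

`adindex` implements the **Air Discussion Index (ADI)**: a fully automatic
pipeline that discovers character-bigram terms whose daily posting frequency
tracks a city's PM₂.₅ concentration, aggregates them into a signed,
standardized index, and fits a linear model that estimates daily PM₂.₅ from
the index alone.

It is aimed at researchers in digital epidemiology / infoveillance who want a
text-derived proxy for ambient air quality where monitor data are sparse,
censored, or unreliable — and at anyone who wants a compact, well-tested
reference implementation of the method to study or extend.

## The method

Inputs are timestamped, city-tagged posts and a daily pollutant series
(hourly monitor readings are averaged over hours 00–23). The pipeline:

1. **Deduplicate.** Exact-duplicate posts (automated "posting machines") are
   collapsed by MD5 content digest within each (city, day).
2. **Term frequencies.** Every length-*n* character window (default *n* = 2,
   bigrams — no dictionary segmentation, so neologisms and mixed scripts are
   covered) is counted at most once per post, giving the daily fraction

   *f*(term, *t*) = (# posts containing term on day *t*) / (# posts on day *t*).

   Terms appearing on average less than once per day are dropped.
3. **Term scoring (STL).** For each candidate term, a one-term linear model
   PM*_t* = α₀ + α₁ *f*(term, *t*) + ε is assessed by four-fold blocked
   cross-validation over the days; the term's score is the mean Pearson
   correlation between held-out estimates and observed PM, and its sign is
   sign(α₁). Ranking by score yields the **Sorted Term List**.
4. **Index and selection (FTS).** Each term's fraction vector is z-scored
   (mean 0, variance 1) and the index is the signed sum

   ADI*_t* = Σ_{term ∈ TS} sign(term) · z(*f*(term, *t*)).

   Scanning the STL top-*N* in rank order, a term is kept only if it strictly
   improves the blocked-CV score of PM*_t* = β₀ + β₁ ADI*_t* + ε; the
   survivors are the **Final Term Set**.
5. **Estimation.** The final linear model is fitted on a learning period and
   applied to a held-out validation period; performance is the Pearson
   correlation between estimated and observed PM₂.₅ on each period.

Because the corpora such a study needs (hundreds of millions of posts) are
not shippable, the package includes a first-class synthetic-corpus generator
that plants a heavy-tailed AR(1) PM₂.₅ series, noise vocabulary, positively
and negatively coupled signal terms, and ~10% duplicate posts — so every
stage is testable end to end and recovery of the planted structure is
measurable.

## Worked example

```bash
python examples/select_and_estimate.py
```

builds a small synthetic corpus (120 days, ~500 posts/day, 5 positive + 5
negative signal terms among 300 noise terms), runs the full pipeline with the
last 24 days held out, and prints:

```
city=synthville  terms_in_FTS=7  valid_days=96+24  R_learning=0.956  R_validation=0.944
final model: PM = 85.6 + 7.3 * ADI
FTS terms: ['偘偙', '做偛', '偞偟', '偠偡', '偨偩', '偦偧', '偢偣'] (7 of them planted signal terms)

validation days (estimated vs observed ug/m3):
  2012-04-06    156.5  vs    164.9
  2012-04-07     79.1  vs     77.7
  ...
```

All seven selected terms are planted signal terms, and the index explains the
held-out days with r = 0.944: the greedy selection found the real coupling,
not noise. `examples/generate_corpus.py` and `examples/score_terms.py` show
the generator and the term-ranking stage on their own.

The same pipeline is available from the shell:

```bash
adindex generate --out data/ --seed 42
adindex run --posts data/posts.jsonl --pm data/pm.csv --city synthville \
            --split-date 2012-11-16 --out results/
```

which writes `stl.tsv`, `fts.tsv`, `adi.csv`, `estimates.csv`, `report.json`
and the resolved configuration. `adindex score / select / estimate /
evaluate` run the stages separately from each other's exported files.

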