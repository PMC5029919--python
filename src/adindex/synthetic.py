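"""Synthetic post corpora and pollutant series with planted term-PM coupling.

The generator emulates the statistical shape the index method assumes, at
desk scale: a heavy-tailed, autocorrelated daily PM2.5 series (lognormal
AR(1) with occasional extreme days); tens of thousands of posts per day; a
large vocabulary of two-character noise terms posted at a constant base rate;
a small set of signal terms whose per-post inclusion probability co-varies
(positively or negatively) with the standardized PM series; and ~10%
exact-duplicate posts mimicking automated posting machines.

Posts are concatenations of the sampled terms without separators, so
character-bigram extraction recovers the planted terms plus spurious
boundary bigrams — deliberately stressing the tokenizer the way running text
does.  Every character is unique to one vocabulary term, so boundary bigrams
never collide with planted terms and are individually rare enough to fall
below the once-per-day candidate threshold at the default scale.  A
separator mode (terms joined by spaces) is available for clean unit tests.

All randomness flows from a single integer seed; corpora are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np

from .corpus_io import PollutantSeries, PostRecord

logger = logging.getLogger(__name__)

_CHAR_BASE = 0x4E00  # CJK Unified Ideographs: plausible-looking two-char terms


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    Defaults emulate a single city at desk scale: 400 days, ~2000 posts/day,
    2000 noise terms, 20 positive + 20 negative signal terms at coupling 0.8,
    10% duplicated posts, and a lognormal AR(1) PM series with mean ~100
    ug/m3 and occasional extreme days.
    """

    n_days: int = 400
    posts_per_day_mean: float = 2000.0
    vocab_noise_size: int = 2000
    n_signal_pos: int = 20
    n_signal_neg: int = 20
    signal_strength: float = 0.8
    base_term_rate: float = 0.002
    duplicate_rate: float = 0.10
    pm_log_mean: float = 4.44  # exp(4.44 + 0.5^2/2) ~ 96 ug/m3 before extremes
    pm_log_sd: float = 0.5
    pm_ar1: float = 0.7
    extreme_day_prob: float = 0.035
    extreme_multiplier: float = 2.5
    start: date = date(2012, 1, 1)
    city: str = "synthville"
    separator: str = ""  # " " gives whitespace-delimited terms for clean unit tests
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_term_rate", "duplicate_rate", "extreme_day_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 < self.pm_ar1 < 1.0:
            raise ValueError("pm_ar1 must lie in (-1, 1)")
        if min(self.n_days, self.vocab_noise_size, self.n_signal_pos, self.n_signal_neg) < 0:
            raise ValueError("counts must be >= 0")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")

    def days(self) -> list[date]:
        return [self.start + timedelta(days=i) for i in range(self.n_days)]


@dataclass
class GroundTruth:
    """Oracle record of what was planted, for parameter-recovery tests."""

    pm_series: PollutantSeries
    pm_z: dict[date, float]
    signal_terms: dict[str, int]  # term -> planted sign
    term_rates: dict[str, dict[date, float]]  # signal terms' daily inclusion rates
    base_term_rate: float
    vocabulary: list[str]

    @property
    def noise_terms(self) -> list[str]:
        return [t for t in self.vocabulary if t not in self.signal_terms]

    def rate(self, term: str, d: date) -> float:
        if term in self.term_rates:
            return self.term_rates[term][d]
        return self.base_term_rate

    def write_json(self, path) -> None:
        payload = {
            "city": self.pm_series.city,
            "pm": {d.isoformat(): v for d, v in self.pm_series.observations.items()},
            "pm_z": {d.isoformat(): v for d, v in self.pm_z.items()},
            "signal_terms": self.signal_terms,
            "base_term_rate": self.base_term_rate,
            "vocabulary": self.vocabulary,
            "term_rates": {
                t: {d.isoformat(): r for d, r in rates.items()}
                for t, rates in self.term_rates.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False)


def make_vocabulary(config: SyntheticConfig) -> tuple[list[str], dict[str, int]]:
    """Two-character terms over disjoint characters; signal terms come last.

    Returns (vocabulary, signal_terms) where signal_terms maps term -> sign.
    """
    n_total = config.vocab_noise_size + config.n_signal_pos + config.n_signal_neg
    if 2 * n_total > 0x9FFF - _CHAR_BASE:
        raise ValueError("vocabulary too large for the character block")
    vocab = [chr(_CHAR_BASE + 2 * i) + chr(_CHAR_BASE + 2 * i + 1) for i in range(n_total)]
    signal = {}
    for i in range(config.n_signal_pos):
        signal[vocab[config.vocab_noise_size + i]] = +1
    for i in range(config.n_signal_neg):
        signal[vocab[config.vocab_noise_size + config.n_signal_pos + i]] = -1
    return vocab, signal


def generate_pm(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[PollutantSeries, dict[date, float]]:
    """Lognormal AR(1) daily PM series with extreme days, plus its z-scores.

    log P_t = mu + phi*(log P_{t-1} - mu) + eps_t with eps_t ~ N(0, sd^2*(1-phi^2)),
    so the stationary sd of log P is pm_log_sd.  With probability
    extreme_day_prob a day is multiplied by extreme_multiplier.  The returned
    z-scores standardize the concentration series itself (level scale,
    population convention) over the generated days and are the covariate the
    signal terms couple to: discussion responds to how unusual the day's
    concentration is, with extreme days pulling hardest.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu, sd, phi = config.pm_log_mean, config.pm_log_sd, config.pm_ar1
    n = config.n_days
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    logp = np.empty(n)
    prev = mu + sd * rng.standard_normal() if sd > 0 else mu
    for t in range(n):
        prev = mu + phi * (prev - mu) + innov_sd * rng.standard_normal()
        logp[t] = prev
    extreme = rng.random(n) < config.extreme_day_prob
    pm = np.exp(logp)
    pm[extreme] *= config.extreme_multiplier
    if np.all(pm == pm[0]):  # exact constancy; sd can round off to ~1e-14
        z = np.zeros(n)
    else:
        z = (pm - pm.mean()) / pm.std()
    days = config.days()
    series = PollutantSeries(
        city=config.city,
        observations={d: float(v) for d, v in zip(days, pm)},
        provenance="synthetic",
    )
    return series, {d: float(v) for d, v in zip(days, z)}


def generate_posts(
    config: SyntheticConfig,
    pm_z: dict[date, float],
    rng: np.random.Generator | None = None,
) -> tuple[list[PostRecord], GroundTruth]:
    """Sample a post corpus whose signal-term frequencies track the PM z-scores.

    Per day: post count ~ Poisson(posts_per_day_mean); each vocabulary term
    enters each post independently — noise terms at base_term_rate, a signal
    term of sign s at clamp(base_term_rate*(1 + s*signal_strength*z_t), 0, 1).
    Posts that drew no terms at all are dropped.  Finally each post is, with
    probability duplicate_rate, replaced by a copy of another (unreplaced)
    same-day post, planting the exact duplicates that dedup should remove.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vocab, signal = make_vocabulary(config)
    vocab_arr = np.array(vocab, dtype="<U2")
    n_vocab = len(vocab)
    signs = np.zeros(n_vocab)
    for i, t in enumerate(vocab):
        if t in signal:
            signs[i] = signal[t]

    posts: list[PostRecord] = []
    term_rates: dict[str, dict[date, float]] = {t: {} for t in signal}
    noon = time(12, 0, 0)
    sep = config.separator
    for d in sorted(pm_z):
        z = pm_z[d]
        rates = np.clip(config.base_term_rate * (1.0 + signs * config.signal_strength * z), 0.0, 1.0)
        for t_i, t in enumerate(vocab):
            if t in signal:
                term_rates[t][d] = float(rates[t_i])
        n_posts = int(rng.poisson(config.posts_per_day_mean))
        if n_posts == 0:
            continue
        include = rng.random((n_posts, n_vocab), dtype=np.float32) < rates.astype(np.float32)
        counts = include.sum(axis=1)
        rows, cols = np.nonzero(include)  # row-major: cols grouped by post, vocab order
        pieces = np.split(vocab_arr[cols], np.cumsum(counts)[:-1])
        texts = [sep.join(p) for p in pieces]
        keep = [i for i, c in enumerate(counts) if c > 0]
        texts = [texts[i] for i in keep]
        n_kept = len(texts)
        if n_kept == 0:
            continue
        # plant exact duplicates: replaced posts copy an unreplaced same-day post
        dup_mask = rng.random(n_kept) < config.duplicate_rate
        originals = np.nonzero(~dup_mask)[0]
        replaced = np.nonzero(dup_mask)[0]
        if originals.size and replaced.size:
            src = originals[rng.integers(0, originals.size, size=replaced.size)]
            for i, j in zip(replaced, src):
                texts[i] = texts[j]
        ts = datetime.combine(d, noon)
        day_tag = d.isoformat()
        posts.extend(
            PostRecord(post_id=f"{config.city}-{day_tag}-{k:05d}", timestamp=ts,
                       city=config.city, text=txt)
            for k, txt in enumerate(texts)
        )
    logger.info("generate_posts: %d post(s) over %d day(s)", len(posts), len(pm_z))
    truth = GroundTruth(
        pm_series=PollutantSeries(city=config.city, observations={}, provenance="placeholder"),
        pm_z=dict(pm_z),
        signal_terms=dict(signal),
        term_rates=term_rates,
        base_term_rate=config.base_term_rate,
        vocabulary=vocab,
    )
    return posts, truth


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[PostRecord], PollutantSeries, GroundTruth]:
    """Full corpus: PM series, z-scores, and the coupled post stream."""
    root = np.random.default_rng(config.seed)
    pm_rng, post_rng = (np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, size=2))
    series, pm_z = generate_pm(config, pm_rng)
    posts, truth = generate_posts(config, pm_z, post_rng)
    truth.pm_series = series
    return posts, series, truth
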