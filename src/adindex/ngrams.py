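"""Character n-gram extraction and daily term-fraction tables.

The unit term is an n-character sliding window over running text (default
n = 2, i.e. character bigrams), not a dictionary word: this sidesteps Chinese
word segmentation and captures neologisms.  Windows never span whitespace, a
term is counted at most once per post, and the per-day statistic is the
fraction of that day's posts containing the term:

    f(term, date, city) = post_count(term, date, city) / base_post_count(date, city)

Storage is sparse (term -> {date: count}) so corpora with millions of distinct
terms never materialize a dense term x day matrix.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np

from .corpus_io import PostRecord

logger = logging.getLogger(__name__)


def extract_ngrams(text: str, n: int = 2) -> set[str]:
    """Set of all length-``n`` character windows of ``text``.

    Windows spanning any whitespace character are excluded (whitespace breaks
    the window), and repeats within one post collapse: a term is counted once
    per post no matter how often it recurs.  Text shorter than ``n`` yields the
    empty set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grams: set[str] = set()
    for seg in text.split():
        if len(seg) >= n:
            grams.update(seg[i : i + n] for i in range(len(seg) - n + 1))
    return grams


@dataclass
class TermFractionTable:
    """Sparse per-(term, date) post counts and per-day base counts for one city."""

    city: str
    base_post_count: dict[date, int]
    counts: dict[str, dict[date, int]]
    n: int = 2

    def __post_init__(self) -> None:
        self.base_post_count = dict(sorted(self.base_post_count.items()))

    def dates(self) -> list[date]:
        return list(self.base_post_count)

    def terms(self) -> list[str]:
        return list(self.counts)

    def total_count(self, term: str, dates: Sequence[date] | None = None) -> int:
        per_day = self.counts.get(term, {})
        if dates is None:
            return sum(per_day.values())
        return sum(per_day.get(d, 0) for d in dates)

    def fraction(self, term: str, d: date) -> float:
        base = self.base_post_count.get(d)
        if not base:
            return 0.0
        return self.counts.get(term, {}).get(d, 0) / base

    def fraction_vector(self, term: str, dates: Sequence[date]) -> np.ndarray:
        per_day = self.counts.get(term, {})
        return np.array(
            [per_day.get(d, 0) / self.base_post_count[d] for d in dates], dtype=float
        )

    def write_tsv(self, path) -> None:
        """Long-format export: term, date, count, base_count, fraction."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["term", "date", "count", "base_count", "fraction"])
            for term in sorted(self.counts):
                for d, c in sorted(self.counts[term].items()):
                    base = self.base_post_count[d]
                    w.writerow([term, d.isoformat(), c, base, repr(c / base)])

    @classmethod
    def read_tsv(cls, path, city: str = "", n: int = 2) -> "TermFractionTable":
        counts: dict[str, dict[date, int]] = {}
        base: dict[date, int] = {}
        with open(path, encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                d = date.fromisoformat(row["date"])
                counts.setdefault(row["term"], {})[d] = int(row["count"])
                base[d] = int(row["base_count"])
        return cls(city=city, base_post_count=base, counts=counts, n=n)


def build_fraction_table(
    posts: Sequence[PostRecord],
    city: str,
    n: int = 2,
    min_total_count: int | None = None,
) -> TermFractionTable:
    """Count, per (term, date), the number of posts containing each n-gram.

    ``posts`` must already be deduplicated and belong to ``city`` (others are
    rejected).  ``min_total_count`` enables a memory-saving two-pass mode that
    drops terms whose whole-corpus post count falls below the bound before the
    per-day table is materialized; it must be no larger than any downstream
    candidate threshold, so it can only prune terms the threshold would drop
    anyway.
    """
    for p in posts:
        if p.city != city:
            raise ValueError(f"post {p.post_id} belongs to {p.city!r}, not {city!r}")

    base: dict[date, int] = {}
    keep: set[str] | None = None
    if min_total_count is not None and min_total_count > 1:
        totals: Counter[str] = Counter()
        for p in posts:
            totals.update(extract_ngrams(p.text, n))
        keep = {t for t, c in totals.items() if c >= min_total_count}
        logger.info(
            "build_fraction_table: prefilter kept %d of %d terms (min_total_count=%d)",
            len(keep), len(totals), min_total_count,
        )
        del totals

    per_day: dict[date, Counter] = {}
    for p in posts:
        d = p.day
        base[d] = base.get(d, 0) + 1
        grams = extract_ngrams(p.text, n)
        if keep is not None:
            grams &= keep
        if grams:
            per_day.setdefault(d, Counter()).update(grams)

    counts: dict[str, dict[date, int]] = {}
    for d in sorted(per_day):
        for term, c in per_day[d].items():
            counts.setdefault(term, {})[d] = c
    return TermFractionTable(city=city, base_post_count=base, counts=counts, n=n)


def filter_candidates(
    table: TermFractionTable,
    total_days: int,
    dates: Sequence[date] | None = None,
    strict: bool = False,
) -> set[str]:
    """Terms appearing on average at least once per day over the dataset.

    Keeps terms whose total post count (over ``dates`` if given, else the whole
    table) is >= ``total_days``; ``strict=True`` switches the boundary to >.
    """
    if total_days < 1:
        raise ValueError("total_days must be >= 1")
    out = set()
    for term in table.counts:
        tot = table.total_count(term, dates)
        if tot > total_days or (not strict and tot == total_days):
            out.add(term)
    logger.info("filter_candidates: %d of %d terms pass the once-per-day threshold",
                len(out), len(table.counts))
    return out
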