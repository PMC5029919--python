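"""The Air Discussion Index: signed sums of standardized term frequencies.

Because raw term frequencies span orders of magnitude, each selected term's
daily-fraction vector is standardized to mean 0, variance 1 (population
convention) before aggregation; the index on a day is the sum of the selected
terms' z-scores, each weighted by its sign (+1 if the term's frequency rises
with PM, -1 if it falls):

    ADI_t = sum_{term in TS} sign(term) * z(f(term, t))

A term set is evaluated by blocked four-fold cross-validation: the aligned
dates are divided into four contiguous sections; for each section a linear
model PM = b0 + b1*ADI is learned on the complementary dates and the section's
score is the Pearson correlation between the model's estimates and observed PM
on the held-out section; the term set's score is the mean of the four.

The Final Term Set is chosen greedily: scan the Sorted Term List in rank
order, tentatively adding each term and keeping it only if the evaluation
score strictly improves on the best score seen so far.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import DateRange, PollutantSeries
from .ngrams import TermFractionTable
from .scoring import SortedTermList, contiguous_folds, fit_ols, pearson

logger = logging.getLogger(__name__)

TermSet = Sequence[tuple[str, int]]  # (term, sign) pairs


def znormalize(v, return_flag: bool = False):
    """Standard score of a vector: mean 0, variance 1 (population convention).

    A constant vector is degenerate: the zero vector is returned (the term
    contributes nothing to the index) and, with ``return_flag=True``, flagged.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("znormalize needs at least 2 values")
    # exact-constancy test, not sd == 0: roundoff in the mean can leave a
    # spurious ~1e-17 sd on constant input, which would explode the division
    if np.all(v == v[0]):
        logger.debug("znormalize: constant vector; returning zeros")
        z, flag = np.zeros_like(v), True
    else:
        mean = v.mean()
        sd = float(np.sqrt(np.mean((v - mean) ** 2)))
        z, flag = (v - mean) / sd, False
    return (z, flag) if return_flag else z


def term_stats(
    table: TermFractionTable, terms: Sequence[str], reference_dates: Sequence[date]
) -> dict[str, tuple[float, float]]:
    """Per-term (mean, population sd) of the daily fraction over a reference period.

    Computing these on the learning period only, then applying them to later
    dates, keeps the index construction free of target leakage.
    """
    stats = {}
    for t in terms:
        f = table.fraction_vector(t, reference_dates)
        if f.size and np.all(f == f[0]):  # exactly constant: flag via sd = 0
            stats[t] = (float(f[0]), 0.0)
        else:
            stats[t] = (float(f.mean()), float(np.sqrt(np.mean((f - f.mean()) ** 2))))
    return stats


@dataclass
class ADISeries:
    """Daily index values for one city under a fixed signed term set."""

    city: str
    term_set: list[tuple[str, int]]
    values: dict[date, float]

    def dates(self) -> list[date]:
        return list(self.values)

    def vector(self, dates: Sequence[date] | None = None) -> np.ndarray:
        if dates is None:
            dates = self.dates()
        return np.array([self.values[d] for d in dates], dtype=float)

    def write_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["date", "adi_value"])
            for d, v in sorted(self.values.items()):
                w.writerow([d.isoformat(), repr(v)])


def _check_terms(table: TermFractionTable, term_set: TermSet) -> None:
    for t, s in term_set:
        if t not in table.counts:
            raise KeyError(f"term {t!r} missing from fraction table")
        if s not in (+1, -1):
            raise ValueError(f"sign for {t!r} must be +1 or -1")


def adi_naive(table: TermFractionTable, term_set: TermSet, dates: Sequence[date] | None = None) -> ADISeries:
    """Unstandardized variant: signed sum of raw daily fractions (for comparison only)."""
    _check_terms(table, term_set)
    if dates is None:
        dates = table.dates()
    values = {}
    for d in dates:
        values[d] = float(sum(s * table.fraction(t, d) for t, s in term_set))
    return ADISeries(city=table.city, term_set=list(term_set), values=values)


def adi(
    table: TermFractionTable,
    term_set: TermSet,
    dates: Sequence[date] | None = None,
    stats: Mapping[str, tuple[float, float]] | None = None,
) -> ADISeries:
    """Signed sum of z-standardized term fractions over ``dates``.

    ``stats`` supplies per-term (mean, sd) from a declared reference period;
    when omitted they are computed over ``dates`` themselves.  Terms with zero
    variance contribute nothing.  An empty term set yields the all-zero series.
    """
    _check_terms(table, term_set)
    if dates is None:
        dates = table.dates()
    dates = list(dates)
    total = np.zeros(len(dates))
    if term_set:
        if stats is None:
            stats = term_stats(table, [t for t, _ in term_set], dates)
        for t, s in term_set:
            mean, sd = stats[t]
            if sd == 0.0:
                continue
            total = total + s * (table.fraction_vector(t, dates) - mean) / sd
    return ADISeries(city=table.city, term_set=list(term_set),
                     values={d: float(v) for d, v in zip(dates, total)})


@dataclass
class EvaluationResult:
    """Blocked four-fold evaluation of a term set: per-section and mean held-out r."""

    section_r: tuple[float, ...]
    mean_r: float
    section_boundaries: tuple[DateRange, ...]


def evaluate_vectors(adi_vec, p_vec, folds: int = 4) -> tuple[list[float], float]:
    """Core of the term-set evaluator on raw aligned vectors.

    Splits into ``folds`` contiguous sections; per section, fits PM on ADI
    over the complementary points and correlates held-out estimates with
    observations.  Degenerate sections (constant estimates or observations)
    score 0.  Returns (section_r, mean_r).
    """
    adi_vec = np.asarray(adi_vec, dtype=float)
    p_vec = np.asarray(p_vec, dtype=float)
    if adi_vec.shape != p_vec.shape:
        raise ValueError("ADI and PM vectors must align")
    n = adi_vec.size
    if n < 2 * folds:
        raise ValueError(f"need >= {2 * folds} aligned days, got {n}")
    section_r = []
    for block in contiguous_folds(n, folds):
        train = np.setdiff1d(np.arange(n), block)
        fit = fit_ols(adi_vec[train], p_vec[train])
        section_r.append(pearson(fit.predict(adi_vec[block]), p_vec[block]))
    return section_r, float(np.mean(section_r))


def evaluate(
    term_set: TermSet,
    table: TermFractionTable,
    series: PollutantSeries,
    dates: Sequence[date] | None = None,
    folds: int = 4,
    stats: Mapping[str, tuple[float, float]] | None = None,
) -> EvaluationResult:
    """Evaluate a signed term set by blocked cross-validation on the aligned dates."""
    if dates is None:
        dates = sorted(set(table.base_post_count) & set(series.observations))
    dates = list(dates)
    index = adi(table, term_set, dates=dates, stats=stats)
    section_r, mean_r = evaluate_vectors(index.vector(dates), series.values_for(dates), folds)
    boundaries = tuple(
        DateRange(dates[b[0]], dates[b[-1]], label=f"section{i+1}")
        for i, b in enumerate(contiguous_folds(len(dates), folds))
    )
    return EvaluationResult(section_r=tuple(section_r), mean_r=mean_r, section_boundaries=boundaries)


@dataclass
class FinalTermSet:
    """Outcome of the greedy scan: accepted (term, sign, stl_rank) plus the score trace."""

    city: str
    entries: list[tuple[str, int, int]]
    best_score: float
    trace: list[float] = field(default_factory=list)  # best score after each scanned term

    @property
    def term_set(self) -> list[tuple[str, int]]:
        return [(t, s) for t, s, _ in self.entries]

    @property
    def terms(self) -> list[str]:
        return [t for t, _, _ in self.entries]

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["term", "sign", "stl_rank"])
            for t, s, r in self.entries:
                w.writerow([t, s, r])

    @classmethod
    def read_tsv(cls, path, city: str = "") -> "FinalTermSet":
        entries = []
        with open(path, encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                entries.append((row["term"], int(row["sign"]), int(row["stl_rank"])))
        return cls(city=city, entries=entries, best_score=float("nan"))


def select_term_set(
    stl: SortedTermList,
    table: TermFractionTable,
    series: PollutantSeries,
    top_n: int = 500,
    dates: Sequence[date] | None = None,
    folds: int = 4,
) -> FinalTermSet:
    """Greedy forward selection of the Final Term Set from the top of the STL.

    Scans the top ``top_n`` STL entries in rank order with an initially empty
    set and best score 0; each term is tentatively added and kept only if the
    blocked-CV evaluation score strictly increases.  The accepted-score trace
    is therefore monotone non-decreasing.  Standardization statistics are the
    per-term mean/sd over ``dates`` (the selection period), so the incremental
    index update is exact.
    """
    if not stl.entries:
        raise ValueError("STL is empty")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if dates is None:
        dates = sorted(set(table.base_post_count) & set(series.observations))
    dates = list(dates)
    p_vec = series.values_for(dates)

    current = np.zeros(len(dates))
    best = 0.0
    entries: list[tuple[str, int, int]] = []
    trace: list[float] = []
    for rank, entry in enumerate(stl.top(top_n), start=1):
        z = znormalize(table.fraction_vector(entry.term, dates))
        candidate = current + entry.sign * z
        _, mean_r = evaluate_vectors(candidate, p_vec, folds)
        if mean_r > best:
            best = mean_r
            current = candidate
            entries.append((entry.term, entry.sign, rank))
        trace.append(best)
    if not entries:
        logger.warning("select_term_set: no term ever improved the score; empty FTS")
    logger.info("select_term_set: %d term(s) accepted of %d scanned; best score %.4f",
                len(entries), len(trace), best)
    return FinalTermSet(city=stl.city, entries=entries, best_score=best, trace=trace)
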