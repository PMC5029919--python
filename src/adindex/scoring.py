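"""Per-term scoring: cross-validated correlation of a one-term linear PM model.

For each candidate term a simple linear regression

    PM_t = alpha0 + alpha1 * f(term, t) + eps

is fitted under four-fold cross-validation over the aligned dates.  The folds
are contiguous blocks of days (matching the blocked evaluation used for term
sets); each fold's score is the Pearson correlation between the model's
held-out PM estimates and the observed PM, and the term's final score is the
mean of the four fold correlations.  The term's sign (+1 / -1) is the sign of
alpha1 fitted on all aligned dates.  Terms ranked by score form the Sorted
Term List (STL).

Note the fold correlation is prediction-vs-observation, so a perfectly
anti-correlated term still scores 1 (its negative slope flips the predictions
back onto PM); the direction of association lives in the sign, not the score.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import PollutantSeries
from .ngrams import TermFractionTable

logger = logging.getLogger(__name__)


def pearson(a, b) -> float:
    """Pearson correlation, defined as 0.0 when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        return 0.0
    da = a - a.mean()
    db = b - b.mean()
    na = float(np.sqrt(da @ da))
    nb = float(np.sqrt(db @ db))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip((da @ db) / (na * nb), -1.0, 1.0))


@dataclass(frozen=True)
class LinearFit:
    """Closed-form OLS fit of y on x: intercept + slope * x.

    ``r`` is the Pearson correlation between fitted values and the data the
    fit was validated against.  ``degenerate`` flags a constant predictor, for
    which the slope is 0, the intercept is mean(y) and r is defined as 0.
    """

    intercept: float
    slope: float
    r: float = 0.0
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_ols(x, y) -> LinearFit:
    """Ordinary least squares via the normal equations.

    Requires at least 3 points.  A constant predictor yields the degenerate
    fit (slope 0, intercept mean(y), r = 0) rather than an error, so that
    uninformative terms are penalized instead of crashing the scan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("fit_ols needs at least 3 points")
    xbar = x.mean()
    dx = x - xbar
    sxx = float(dx @ dx)
    if sxx == 0.0:
        logger.debug("fit_ols: constant predictor; degenerate fit")
        return LinearFit(intercept=float(y.mean()), slope=0.0, r=0.0, degenerate=True)
    slope = float(dx @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * xbar)
    fit = LinearFit(intercept=intercept, slope=slope)
    return LinearFit(intercept=intercept, slope=slope, r=pearson(fit.predict(x), y))


def contiguous_folds(n: int, folds: int = 4) -> list[np.ndarray]:
    """Partition indices 0..n-1 into ``folds`` contiguous near-equal blocks.

    Remainders go to the earliest blocks; blocks are non-overlapping and
    exhaustive.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot split {n} points into {folds} folds")
    sizes = np.full(folds, n // folds, dtype=int)
    sizes[: n % folds] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[i], edges[i + 1]) for i in range(folds)]


@dataclass(frozen=True)
class TermScore:
    """A term's cross-validated score: mean of per-fold held-out correlations."""

    term: str
    fold_r: tuple[float, ...]
    score: float
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")


def score_term(
    f_vec,
    p_vec,
    folds: int = 4,
    term: str = "",
    scheme: str = "contiguous",
    rng: np.random.Generator | None = None,
) -> TermScore:
    """Score one term by blocked cross-validation of its one-term PM model.

    ``scheme="contiguous"`` (default) uses chronological blocks; ``"random"``
    shuffles the dates first (requires ``rng``).  A fold whose predictions or
    observations are constant contributes r = 0.
    """
    f_vec = np.asarray(f_vec, dtype=float)
    p_vec = np.asarray(p_vec, dtype=float)
    if f_vec.shape != p_vec.shape:
        raise ValueError("fraction and PM vectors must align on the same dates")
    n = f_vec.size
    if n < folds:
        raise ValueError(f"need at least {folds} aligned days, got {n}")
    order = np.arange(n)
    if scheme == "random":
        if rng is None:
            raise ValueError("random fold scheme requires rng")
        order = rng.permutation(n)
    elif scheme != "contiguous":
        raise ValueError(f"unknown fold scheme {scheme!r}")

    fold_r = []
    for block in contiguous_folds(n, folds):
        test = order[block]
        train = np.setdiff1d(order, test)
        fit = fit_ols(f_vec[train], p_vec[train])
        pred = fit.predict(f_vec[test])
        fold_r.append(pearson(pred, p_vec[test]))
    full = fit_ols(f_vec, p_vec)
    sign = 1 if full.slope >= 0 else -1
    return TermScore(term=term, fold_r=tuple(fold_r), score=float(np.mean(fold_r)), sign=sign)


@dataclass
class SortedTermList:
    """All candidate terms of a city ranked by cross-validated score (descending)."""

    city: str
    entries: list[TermScore]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (-e.score, e.term))

    def top(self, n: int) -> list[TermScore]:
        return self.entries[:n]

    def rank_of(self, term: str) -> int:
        """1-based rank; raises KeyError if absent."""
        for i, e in enumerate(self.entries, start=1):
            if e.term == term:
                return i
        raise KeyError(term)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["rank", "term", "score", "sign"] +
                       [f"fold_r{i+1}" for i in range(len(self.entries[0].fold_r) if self.entries else 4)])
            for i, e in enumerate(self.entries, start=1):
                w.writerow([i, e.term, repr(e.score), e.sign] + [repr(r) for r in e.fold_r])

    @classmethod
    def read_tsv(cls, path, city: str = "") -> "SortedTermList":
        entries = []
        with open(path, encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            fold_cols = [c for c in reader.fieldnames or [] if c.startswith("fold_r")]
            for row in reader:
                entries.append(
                    TermScore(
                        term=row["term"],
                        fold_r=tuple(float(row[c]) for c in fold_cols),
                        score=float(row["score"]),
                        sign=int(row["sign"]),
                    )
                )
        return cls(city=city, entries=entries)


def build_stl(
    table: TermFractionTable,
    series: PollutantSeries,
    candidates: Iterable[str],
    dates: Sequence[date] | None = None,
    folds: int = 4,
) -> SortedTermList:
    """Score every candidate term and rank them into the Sorted Term List.

    ``dates`` defaults to the aligned dates (table days with a pollutant
    observation).  Ties in score break lexicographically on the term, so the
    ordering is reproducible bit-for-bit.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    if dates is None:
        dates = sorted(set(table.base_post_count) & set(series.observations))
    if len(dates) < 2 * folds:
        raise ValueError(f"need >= {2 * folds} aligned days, got {len(dates)}")
    p_vec = series.values_for(dates)
    entries = [
        score_term(table.fraction_vector(t, dates), p_vec, folds=folds, term=t)
        for t in candidates
    ]
    return SortedTermList(city=table.city, entries=entries)
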