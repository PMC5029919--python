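"""Final linear model: daily PM2.5 estimated from the Air Discussion Index.

With the Final Term Set fixed, a single linear model

    PM_t = beta0 + beta1 * ADI_t + eps

is fitted on the learning period and applied to the held-out validation
period; performance is reported as the Pearson correlation between estimated
and observed PM on each period separately.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np

from .adi_index import ADISeries
from .corpus_io import DateRange, PollutantSeries
from .scoring import LinearFit, fit_ols, pearson

logger = logging.getLogger(__name__)


class EstimationError(ValueError):
    pass


def fit_final_model(index: ADISeries, series: PollutantSeries, learning: DateRange) -> LinearFit:
    """OLS fit of observed PM on the ADI over the learning-period aligned dates."""
    dates = [d for d in index.values if d in learning and d in series.observations]
    if len(dates) < 10:
        raise EstimationError(f"only {len(dates)} aligned learning day(s); need >= 10")
    x = index.vector(dates)
    y = series.values_for(dates)
    fit = fit_ols(x, y)
    if fit.degenerate:
        raise EstimationError("ADI is constant over the learning period; cannot fit")
    return fit


def estimate(
    fit: LinearFit, index: ADISeries, dates: Sequence[date] | DateRange
) -> dict[date, float]:
    """Apply the learned model: beta0 + beta1 * ADI per date.

    Negative estimates are physically impossible concentrations but are
    retained (and logged) so correlation diagnostics stay undistorted; use
    :func:`clip_nonnegative` for presentation.
    """
    if isinstance(dates, DateRange):
        dates = [d for d in index.values if d in dates]
    out = {d: float(fit.intercept + fit.slope * index.values[d]) for d in dates}
    n_neg = sum(v < 0 for v in out.values())
    if n_neg:
        logger.warning("estimate: %d negative PM estimate(s) retained (flag them downstream)", n_neg)
    return out


def clip_nonnegative(estimates: Mapping[date, float]) -> dict[date, float]:
    return {d: max(0.0, v) for d, v in estimates.items()}


@dataclass
class EstimationReport:
    """Learning/validation performance of the final model, one city."""

    city: str
    fts_size: int
    learning_range: DateRange
    validation_range: DateRange
    n_learning: int
    n_validation: int
    r_learning: float | None
    r_validation: float | None
    rmse_validation: float | None
    bias_validation: float | None
    fit: LinearFit
    estimated_series: dict[date, float]  # validation-period estimates

    def to_dict(self) -> dict:
        return {
            "city": self.city,
            "fts_size": self.fts_size,
            "learning_range": [self.learning_range.start.isoformat(), self.learning_range.end.isoformat()],
            "validation_range": [self.validation_range.start.isoformat(), self.validation_range.end.isoformat()],
            "n_learning": self.n_learning,
            "n_validation": self.n_validation,
            "r_learning": self.r_learning,
            "r_validation": self.r_validation,
            "rmse_validation": self.rmse_validation,
            "bias_validation": self.bias_validation,
            "beta0": self.fit.intercept,
            "beta1": self.fit.slope,
        }

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        """Text summary in the shape of a per-city performance table row."""
        fmt = lambda v: "n/a" if v is None else f"{v:.3f}"
        return (
            f"city={self.city}  terms_in_FTS={self.fts_size}  "
            f"valid_days={self.n_learning}+{self.n_validation}  "
            f"R_learning={fmt(self.r_learning)}  R_validation={fmt(self.r_validation)}"
        )


def report(
    estimated: Mapping[date, float],
    observed: PollutantSeries,
    learning: DateRange,
    validation: DateRange,
    city: str = "",
    fts_size: int = 0,
    fit: LinearFit | None = None,
) -> EstimationReport:
    """Correlate estimates with observations separately on each period.

    Pearson r is computed on the dates present in both ``estimated`` and the
    observed series within each range; a validation period with fewer than 3
    such days gets ``r_validation = None`` with a warning.
    """
    if learning.overlaps(validation):
        raise ValueError("learning and validation ranges overlap")

    def _period(rng: DateRange):
        dates = sorted(d for d in estimated if d in rng and d in observed.observations)
        if not dates:
            return dates, None, None, None
        est = np.array([estimated[d] for d in dates])
        obs = observed.values_for(dates)
        r = pearson(est, obs) if len(dates) >= 3 else None
        rmse = float(np.sqrt(np.mean((est - obs) ** 2)))
        bias = float(np.mean(est - obs))
        return dates, r, rmse, bias

    learn_dates, r_learn, _, _ = _period(learning)
    valid_dates, r_valid, rmse_v, bias_v = _period(validation)
    if r_valid is None:
        logger.warning("report: fewer than 3 validation days; r_validation omitted")
    return EstimationReport(
        city=city or observed.city,
        fts_size=fts_size,
        learning_range=learning,
        validation_range=validation,
        n_learning=len(learn_dates),
        n_validation=len(valid_dates),
        r_learning=r_learn,
        r_validation=r_valid,
        rmse_validation=rmse_v,
        bias_validation=bias_v,
        fit=fit if fit is not None else LinearFit(0.0, 0.0),
        estimated_series={d: float(estimated[d]) for d in valid_dates},
    )


def write_estimates_csv(
    estimated: Mapping[date, float],
    observed: PollutantSeries,
    learning: DateRange,
    path,
) -> None:
    """CSV of (date, observed, estimated, split_label, negative_flag)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "observed", "estimated", "split_label", "negative_flag"])
        for d in sorted(estimated):
            obs = observed.observations.get(d, "")
            label = "learning" if d in learning else "validation"
            est = estimated[d]
            w.writerow([d.isoformat(), repr(obs) if obs != "" else "", repr(est), label, int(est < 0)])
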