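"""End-to-end orchestration: ingest -> dedup -> fractions -> STL -> FTS -> fit -> report.

`run_core` is the in-memory pipeline used by the library, tests and the
acceptance script; `run_pipeline` wraps it with file input/output and writes
every artifact (STL, FTS, ADI series, estimates, report, resolved config) to
an output directory so each stage can also be run separately from the CLI.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import yaml

from . import adi_index as adi_mod
from . import corpus_io, estimation, ngrams, scoring

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Configuration of one pipeline run over in-memory inputs.

    ``split_date`` is the last learning day; later aligned dates form the
    validation period.  ``normalization`` is ``"learning"`` (candidate
    threshold and z-score statistics computed on the learning period only,
    the leakage-safe default) or ``"paper-exact"`` (both computed over all
    aligned dates).
    """

    city: str
    split_date: date
    n: int = 2
    dedup_scope: str = "day"
    threshold_strict: bool = False
    top_n: int = 500
    folds: int = 4
    normalization: str = "learning"
    clip_nonnegative: bool = False
    min_hours: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalization not in ("learning", "paper-exact"):
            raise ValueError(f"unknown normalization mode {self.normalization!r}")


@dataclass
class PipelineResult:
    report: estimation.EstimationReport
    stl: scoring.SortedTermList
    fts: adi_mod.FinalTermSet
    adi_series: adi_mod.ADISeries
    table: ngrams.TermFractionTable
    candidates: set[str]
    aligned_dates: list[date]
    learning_dates: list[date]
    validation_dates: list[date]
    estimates: dict[date, float]
    n_posts_in: int = 0
    n_posts_deduped: int = 0

    @property
    def dedup_removed(self) -> int:
        return self.n_posts_in - self.n_posts_deduped


def run_core(
    posts: Sequence[corpus_io.PostRecord],
    series: corpus_io.PollutantSeries,
    params: PipelineParams,
) -> PipelineResult:
    """Run the whole method on in-memory posts and a daily pollutant series."""
    city = params.city
    posts = [p for p in posts if p.city == city]
    n_in = len(posts)
    if not posts:
        raise ValueError(f"no posts for city {city!r}")
    deduped = corpus_io.deduplicate(posts, scope=params.dedup_scope)

    aligned = corpus_io.align(corpus_io.count_posts_by_day(deduped), series)
    learning_dates = [d for d in aligned if d <= params.split_date]
    validation_dates = [d for d in aligned if d > params.split_date]
    if len(learning_dates) < 2 * params.folds:
        raise ValueError(
            f"only {len(learning_dates)} learning day(s) on or before {params.split_date}"
        )
    learning = corpus_io.DateRange(aligned[0], params.split_date, label="learning")
    if validation_dates:
        validation = corpus_io.DateRange(validation_dates[0], aligned[-1], label="validation")
    else:
        day_after = params.split_date + timedelta(days=1)
        validation = corpus_io.DateRange(day_after, day_after, label="validation")
        logger.warning("pipeline: no aligned dates after the split; validation metrics empty")

    threshold_dates = aligned if params.normalization == "paper-exact" else learning_dates
    table = ngrams.build_fraction_table(
        deduped, city, n=params.n, min_total_count=len(learning_dates)
    )
    candidates = ngrams.filter_candidates(
        table, total_days=len(threshold_dates), dates=threshold_dates,
        strict=params.threshold_strict,
    )
    if not candidates:
        raise ValueError("no candidate terms pass the once-per-day threshold")

    stl = scoring.build_stl(table, series, candidates, dates=learning_dates, folds=params.folds)
    fts = adi_mod.select_term_set(
        stl, table, series, top_n=params.top_n, dates=learning_dates, folds=params.folds
    )

    stats_dates = aligned if params.normalization == "paper-exact" else learning_dates
    stats = adi_mod.term_stats(table, fts.terms, stats_dates)
    index = adi_mod.adi(table, fts.term_set, dates=aligned, stats=stats)

    fit = estimation.fit_final_model(index, series, learning)
    estimates = estimation.estimate(fit, index, aligned)
    if params.clip_nonnegative:
        estimates = estimation.clip_nonnegative(estimates)
    rep = estimation.report(
        estimates, series, learning, validation,
        city=city, fts_size=len(fts.entries), fit=fit,
    )
    logger.info("pipeline: %s", rep.summary())
    return PipelineResult(
        report=rep, stl=stl, fts=fts, adi_series=index, table=table,
        candidates=candidates, aligned_dates=aligned,
        learning_dates=learning_dates, validation_dates=validation_dates,
        estimates=estimates, n_posts_in=n_in, n_posts_deduped=len(deduped),
    )


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (flat key: value mapping on disk)."""

    posts_path: str
    pm_path: str
    out_dir: str
    city: str
    split_date: date
    posts_format: str = "jsonl"
    n: int = 2
    dedup_scope: str = "day"
    threshold_strict: bool = False
    top_n: int = 500
    folds: int = 4
    normalization: str = "learning"
    clip_nonnegative: bool = False
    min_hours: int = 18
    seed: int = 0
    log_level: str = "INFO"

    def params(self) -> PipelineParams:
        return PipelineParams(
            city=self.city, split_date=self.split_date, n=self.n,
            dedup_scope=self.dedup_scope, threshold_strict=self.threshold_strict,
            top_n=self.top_n, folds=self.folds, normalization=self.normalization,
            clip_nonnegative=self.clip_nonnegative, min_hours=self.min_hours,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("split_date"), str):
            raw["split_date"] = date.fromisoformat(raw["split_date"])
        return cls(**raw)

    def write_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["split_date"] = self.split_date.isoformat()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline: read inputs, run, write all artifacts to out_dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    posts = corpus_io.read_posts(config.posts_path, format=config.posts_format)
    series = corpus_io.read_pollutant(config.pm_path, city=config.city, min_hours=config.min_hours)
    result = run_core(posts, series, config.params())

    result.stl.write_tsv(out / "stl.tsv")
    result.fts.write_tsv(out / "fts.tsv")
    result.adi_series.write_csv(out / "adi.csv")
    estimation.write_estimates_csv(
        result.estimates, series, result.report.learning_range, out / "estimates.csv"
    )
    result.report.write_json(out / "report.json")
    config.write_yaml(out / "resolved_config.yaml")
    return result
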