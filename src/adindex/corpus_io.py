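"""Reading, validating, deduplicating and aligning post records and pollutant series.

Posts arrive as line-delimited records (JSON object or TSV row per post) with
fields ``post_id, timestamp, city, text``.  Pollutant observations arrive as a
CSV with columns ``city, datetime, value_ugm3`` at hourly or daily resolution;
hourly readings are averaged to daily means over hours 00-23.

Exact-duplicate posts (a known artifact of automated "posting machines") are
collapsed by content digest within each (city, day) group before any counting.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import unicodedata
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """No date carries both posts and a pollutant observation."""


@dataclass(frozen=True)
class PostRecord:
    """A single social-media post attributed to a city on a calendar day."""

    post_id: str
    timestamp: datetime
    city: str
    text: str

    @property
    def day(self) -> date:
        return self.timestamp.date()


@dataclass
class PollutantSeries:
    """Daily pollutant concentrations (ug/m3) for one city.

    ``observations`` maps calendar dates to non-negative concentrations and is
    kept date-sorted; at most one value per date.
    """

    city: str
    observations: dict[date, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for d, v in self.observations.items():
            if v < 0:
                raise ValueError(f"negative concentration {v} on {d}")
        self.observations = dict(sorted(self.observations.items()))

    def dates(self) -> list[date]:
        return list(self.observations)

    def values_for(self, dates: Sequence[date]) -> np.ndarray:
        return np.array([self.observations[d] for d in dates], dtype=float)


@dataclass(frozen=True)
class DateRange:
    """Inclusive calendar-date interval, optionally labelled learning/validation."""

    start: date
    end: date
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} after end {self.end}")

    def __contains__(self, d: object) -> bool:
        return isinstance(d, date) and self.start <= d <= self.end

    def overlaps(self, other: "DateRange") -> bool:
        return self.start <= other.end and other.start <= self.end


def canonical_text(text: str) -> str:
    """NFC-normalize and strip trailing whitespace; no case folding or punctuation removal."""
    return unicodedata.normalize("NFC", text).rstrip()


def text_digest(text: str) -> str:
    """Content-equality key for dedup: MD5 of the canonical UTF-8 encoding.

    Used purely as a collision-free-in-practice equality key; no security claim.
    """
    return hashlib.md5(canonical_text(text).encode("utf-8")).hexdigest()


def _parse_record(fields: Mapping[str, str]) -> PostRecord | None:
    try:
        post_id = str(fields["post_id"])
        city = str(fields["city"]).strip()
        text = str(fields["text"])
        ts = datetime.fromisoformat(str(fields["timestamp"]))
    except (KeyError, TypeError, ValueError):
        return None
    if not city or not text.strip():
        return None
    return PostRecord(post_id=post_id, timestamp=ts, city=city, text=text)


def read_posts(path, format: str = "jsonl") -> list[PostRecord]:
    """Read post records from a line-delimited file.

    ``format`` is ``"jsonl"`` (one JSON object per line) or ``"tsv"`` (header
    row naming post_id/timestamp/city/text).  Records failing validation are
    skipped and counted; the skip count is reported via logging.
    """
    posts: list[PostRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        if format == "jsonl":
            for line in fh:
                line = line.strip("\n")
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError:
                    skipped += 1
                    continue
                rec = _parse_record(obj) if isinstance(obj, dict) else None
                if rec is None:
                    skipped += 1
                else:
                    posts.append(rec)
        elif format == "tsv":
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                rec = _parse_record({k: (v or "") for k, v in row.items()})
                if rec is None:
                    skipped += 1
                else:
                    posts.append(rec)
        else:
            raise ValueError(f"unknown post format {format!r}")
    if skipped:
        logger.warning("read_posts: skipped %d malformed record(s) in %s", skipped, path)
    logger.info("read_posts: %d valid record(s) from %s", len(posts), path)
    return posts


def write_posts(posts: Iterable[PostRecord], path) -> None:
    """Write posts as line-delimited JSON (the format read_posts consumes)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "post_id": p.post_id,
                        "timestamp": p.timestamp.isoformat(),
                        "city": p.city,
                        "text": p.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def deduplicate(posts: Sequence[PostRecord], scope: str = "day") -> list[PostRecord]:
    """Collapse byte-identical posts to their first occurrence, preserving order.

    ``scope="day"`` (default) dedups within each (city, calendar day) group, the
    window in which automated posting machines repeat themselves; ``"global"``
    dedups across all days within a city.
    """
    if scope not in ("day", "global"):
        raise ValueError(f"unknown dedup scope {scope!r}")
    seen: set[tuple] = set()
    out: list[PostRecord] = []
    for p in posts:
        key = (p.city, p.day, text_digest(p.text)) if scope == "day" else (p.city, text_digest(p.text))
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    removed = len(posts) - len(out)
    if removed:
        logger.info("deduplicate: removed %d duplicate post(s) of %d (scope=%s)", removed, len(posts), scope)
    return out


def daily_mean(
    hourly: Iterable[tuple[datetime, float | None]],
    min_hours: int = 18,
    city: str = "",
    provenance: str = "",
) -> PollutantSeries:
    """Average hourly readings (hours 00-23) to daily means.

    Dates with fewer than ``min_hours`` valid readings are omitted (default 18,
    i.e. 75% coverage).  Negative readings are rejected with a warning; ``None``
    marks a missing hour.
    """
    by_day: dict[date, list[float]] = {}
    rejected = 0
    for ts, v in hourly:
        if v is None:
            continue
        if v < 0:
            rejected += 1
            continue
        by_day.setdefault(ts.date(), []).append(float(v))
    if rejected:
        logger.warning("daily_mean: rejected %d negative reading(s)", rejected)
    obs = {d: float(np.mean(vals)) for d, vals in sorted(by_day.items()) if len(vals) >= min_hours}
    return PollutantSeries(city=city, observations=obs, provenance=provenance)


def count_posts_by_day(posts: Iterable[PostRecord]) -> dict[tuple[str, date], int]:
    """Number of posts per (city, calendar day)."""
    counts: dict[tuple[str, date], int] = {}
    for p in posts:
        key = (p.city, p.day)
        counts[key] = counts.get(key, 0) + 1
    return counts


def align(posts_by_day: Mapping[tuple[str, date], int], series: PollutantSeries) -> list[date]:
    """Dates carrying BOTH >=1 post and a pollutant observation for the series' city.

    All downstream fitting is restricted to these valid dates.  Raises
    :class:`AlignmentError` when the intersection is empty.
    """
    post_days = {d for (c, d), n in posts_by_day.items() if c == series.city and n > 0}
    valid = sorted(post_days & set(series.observations))
    if not valid:
        raise AlignmentError(
            f"no overlapping dates for city {series.city!r}: "
            f"{len(post_days)} post day(s), {len(series.observations)} pollutant day(s)"
        )
    return valid


def read_pollutant(path, city: str | None = None, min_hours: int = 18) -> PollutantSeries:
    """Read a pollutant CSV (columns city, datetime, value_ugm3).

    Granularity is auto-detected: if any date carries multiple readings or a
    non-midnight time component, readings are treated as hourly and averaged
    via :func:`daily_mean`; otherwise values are taken as daily.
    """
    rows: list[tuple[str, datetime, float]] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            c = row["city"]
            if city is not None and c != city:
                continue
            rows.append((c, datetime.fromisoformat(row["datetime"]), float(row["value_ugm3"])))
    if not rows:
        raise ValueError(f"no pollutant rows for city {city!r} in {path}")
    cities = {c for c, _, _ in rows}
    if len(cities) > 1:
        raise ValueError(f"pollutant file mixes cities {sorted(cities)}; pass city=")
    the_city = cities.pop()
    dates_seen = [ts.date() for _, ts, _ in rows]
    hourly_like = len(set(dates_seen)) < len(dates_seen) or any(
        ts.hour or ts.minute or ts.second for _, ts, _ in rows
    )
    if hourly_like:
        return daily_mean(((ts, v) for _, ts, v in rows), min_hours=min_hours, city=the_city, provenance=str(path))
    return PollutantSeries(
        city=the_city, observations={ts.date(): v for _, ts, v in rows}, provenance=str(path)
    )


def write_pollutant(series: PollutantSeries, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["city", "datetime", "value_ugm3"])
        for d, v in series.observations.items():
            w.writerow([series.city, d.isoformat(), repr(v)])
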