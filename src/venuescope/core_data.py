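"""Domain records, tabular I/O and calendar-month arithmetic.

Every statistic downstream of this module is denominated in *calendar
months*: the difference between two dates is ``(later.year - earlier.year)
* 12 + (later.month - earlier.month)``, ignoring the day of month.  Two
dates in the same calendar month are 0 months apart.  This convention is
what makes "months since last review" have a mode of 0 for venues reviewed
in the snapshot month, and lets yearly mean lags come out as averages of
small integers.

Records are plain frozen dataclasses; tables travel as CSV (UTF-8, header
row) or JSON-lines.  The column dictionaries are documented in
``docs/data_dictionary.md``.
"""

from __future__ import annotations

import calendar
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_ZIP_RE = re.compile(r"^\d{5}$")

#: Fixed venue-table columns; any other column is an attribute column.
VENUE_COLUMNS = [
    "venue_id",
    "name",
    "address",
    "city",
    "state",
    "zip",
    "categories",
    "platform_closed_flag",
]
REVIEW_COLUMNS = ["venue_id", "review_date"]
TRUTH_COLUMNS = ["venue_id", "verified_opening_date", "verified_status", "source_note"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Python's builtin ``round`` is banker's rounding; the reporting
    convention here is half-up so that e.g. 100*24/31 -> 77.4.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up."""
    return round_half_up(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VenueRecord:
    """One listed business.

    ``attributes`` maps attribute names (e.g. ``credit_cards``, ``wifi``)
    to booleans; a missing key means the platform reported nothing.
    ``platform_closed_flag`` is the crowd-sourced "this place has closed"
    marker.
    """

    venue_id: str
    name: str
    address: str = ""
    city: str = ""
    state: str = ""
    zip: Optional[str] = None
    categories: frozenset[str] = frozenset()
    platform_closed_flag: bool = False
    attributes: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zip is not None and not _ZIP_RE.match(self.zip):
            raise ValueError(f"zip must be 5 digits, got {self.zip!r}")


@dataclass(frozen=True, order=True)
class ReviewRecord:
    """One dated review of one venue (day precision, reviewer dropped)."""

    venue_id: str
    review_date: date


@dataclass(frozen=True)
class GroundTruthRecord:
    """Externally verified facts about one venue.

    At least one of ``verified_opening_date`` / ``verified_status`` must be
    present; ``verified_status`` is ``"open"`` or ``"closed"`` at the
    snapshot date.
    """

    venue_id: str
    verified_opening_date: Optional[date] = None
    verified_status: Optional[str] = None
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.verified_opening_date is None and self.verified_status is None:
            raise ValueError(
                f"ground truth for {self.venue_id!r} has neither opening date nor status"
            )
        if self.verified_status not in (None, "open", "closed"):
            raise ValueError(f"verified_status must be open/closed, got {self.verified_status!r}")


@dataclass(frozen=True, order=True)
class MonthKey:
    """A calendar month (year, month), totally ordered.

    Subtracting two keys gives the signed count of calendar months between
    them; ``shift`` moves by whole months.
    """

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1..12, got {self.month}")

    @classmethod
    def from_date(cls, d: date) -> "MonthKey":
        return cls(d.year, d.month)

    @property
    def index(self) -> int:
        return self.year * 12 + (self.month - 1)

    @classmethod
    def from_index(cls, i: int) -> "MonthKey":
        return cls(i // 12, i % 12 + 1)

    def __sub__(self, other: "MonthKey") -> int:
        return self.index - other.index

    def shift(self, months: int) -> "MonthKey":
        return MonthKey.from_index(self.index + months)

    def first_day(self) -> date:
        return date(self.year, self.month, 1)

    def last_day(self) -> date:
        return date(self.year, self.month, calendar.monthrange(self.year, self.month)[1])

    def n_days(self) -> int:
        return calendar.monthrange(self.year, self.month)[1]

    def __str__(self) -> str:  # e.g. "2014-10"
        return f"{self.year:04d}-{self.month:02d}"


def month_range(start: MonthKey, end: MonthKey) -> Iterator[MonthKey]:
    """Inclusive iterator of months from ``start`` through ``end``."""
    for i in range(start.index, end.index + 1):
        yield MonthKey.from_index(i)


def months_between(earlier: date, later: date) -> int:
    """Calendar-month difference, day-of-month ignored.

    Negative when ``earlier`` is the later date; additive:
    ``months_between(a, b) + months_between(b, c) == months_between(a, c)``.
    """
    return (later.year - earlier.year) * 12 + (later.month - earlier.month)


def snapshot_date(reviews: Sequence[ReviewRecord], override: Optional[date] = None) -> date:
    """The reference date for recency: an explicit override, else the
    latest review date in the dataset."""
    if override is not None:
        return override
    if not reviews:
        raise ValueError("cannot infer a snapshot date from an empty review set")
    return max(r.review_date for r in reviews)


# ---------------------------------------------------------------------------
# attribute summary
# ---------------------------------------------------------------------------


def summarize_attributes(venues: Sequence[VenueRecord]) -> pd.DataFrame:
    """Per-attribute yes counts over the *whole* venue list.

    An absent attribute counts as "no", so every percentage shares the full
    venue count as denominator.  Returns a frame with columns
    ``attribute, count_yes, total, percent`` sorted by attribute name.
    """
    total = len(venues)
    names: set[str] = set()
    for v in venues:
        names.update(v.attributes)
    rows = []
    for name in sorted(names):
        yes = sum(1 for v in venues if v.attributes.get(name) is True)
        rows.append(
            {
                "attribute": name,
                "count_yes": yes,
                "total": total,
                "percent": percent(yes, total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["attribute", "count_yes", "total", "percent"])


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(raw: str, *, default: Optional[bool] = None) -> Optional[bool]:
    s = str(raw).strip().lower()
    if s == "" or s == "na" or s == "none":
        return default
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {raw!r}")


def _parse_date(raw: str, *, context: str) -> date:
    try:
        return date.fromisoformat(str(raw).strip())
    except ValueError as exc:
        raise ValueError(f"{context}: unparseable ISO date {raw!r}") from exc


def _format_bool(b: Optional[bool]) -> str:
    if b is None:
        return ""
    return "true" if b else "false"


def _read_rows(path: str | Path, fmt: str) -> list[dict]:
    path = Path(path)
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return df.to_dict(orient="records")
    if fmt == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        return rows
    raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'jsonl')")


def _write_rows(rows: list[dict], path: str | Path, fmt: str, columns: list[str]) -> None:
    path = Path(path)
    if fmt == "csv":
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps({c: row.get(c, "") for c in columns}, sort_keys=False))
                fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'jsonl')")


# ---------------------------------------------------------------------------
# venue table
# ---------------------------------------------------------------------------


def read_venues(path: str | Path, fmt: str = "csv") -> list[VenueRecord]:
    """Load a venue table.

    Columns beyond the fixed set become boolean attributes.  A malformed
    zip demotes the field to absent with a warning; a missing id or name is
    a hard error naming the row.  Duplicate venue ids are a hard error.
    """
    records: list[VenueRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(_read_rows(path, fmt), start=1):
        venue_id = str(row.get("venue_id", "") or "").strip()
        name = str(row.get("name", "") or "").strip()
        if not venue_id or not name:
            raise ValueError(f"venue row {i}: venue_id and name are required")
        if venue_id in seen:
            raise ValueError(f"venue row {i}: duplicate venue_id {venue_id!r}")
        seen.add(venue_id)
        zip_raw = str(row.get("zip", "") or "").strip()
        zip_code: Optional[str] = None
        if zip_raw:
            if _ZIP_RE.match(zip_raw):
                zip_code = zip_raw
            else:
                logger.warning("venue row %d (%s): malformed zip %r dropped", i, venue_id, zip_raw)
        cats_raw = row.get("categories", "") or ""
        if isinstance(cats_raw, (list, tuple, set, frozenset)):
            categories = frozenset(str(c) for c in cats_raw)
        else:
            categories = frozenset(c.strip() for c in str(cats_raw).split("|") if c.strip())
        attributes: dict[str, bool] = {}
        attr_src = row.get("attributes")
        if isinstance(attr_src, dict):  # JSON-lines nested form
            for k, v in attr_src.items():
                if v is not None:
                    attributes[str(k)] = bool(v)
        for col, raw in row.items():
            if col in VENUE_COLUMNS or col == "attributes":
                continue
            val = _parse_bool(raw) if not isinstance(raw, bool) else raw
            if val is not None:
                attributes[str(col)] = val
        flag_raw = row.get("platform_closed_flag", False)
        flag = flag_raw if isinstance(flag_raw, bool) else bool(_parse_bool(flag_raw, default=False))
        records.append(
            VenueRecord(
                venue_id=venue_id,
                name=name,
                address=str(row.get("address", "") or ""),
                city=str(row.get("city", "") or ""),
                state=str(row.get("state", "") or ""),
                zip=zip_code,
                categories=categories,
                platform_closed_flag=flag,
                attributes=attributes,
            )
        )
    return records


def write_venues(venues: Sequence[VenueRecord], path: str | Path, fmt: str = "csv") -> None:
    attr_names = sorted({k for v in venues for k in v.attributes})
    columns = VENUE_COLUMNS + attr_names
    rows = []
    for v in venues:
        row = {
            "venue_id": v.venue_id,
            "name": v.name,
            "address": v.address,
            "city": v.city,
            "state": v.state,
            "zip": v.zip or "",
            "categories": "|".join(sorted(v.categories)),
            "platform_closed_flag": _format_bool(v.platform_closed_flag),
        }
        for k in attr_names:
            row[k] = _format_bool(v.attributes.get(k))
        rows.append(row)
    _write_rows(rows, path, fmt, columns)


# ---------------------------------------------------------------------------
# review table
# ---------------------------------------------------------------------------


def read_reviews(
    path: str | Path,
    fmt: str = "csv",
    known_venue_ids: Optional[Iterable[str]] = None,
) -> list[ReviewRecord]:
    """Load a review table, sorted by (venue_id, review_date).

    An unparseable date is a hard error naming the row.  When
    ``known_venue_ids`` is given, reviews referencing unknown venues are
    retained but their count is reported via a warning.
    """
    records: list[ReviewRecord] = []
    for i, row in enumerate(_read_rows(path, fmt), start=1):
        venue_id = str(row.get("venue_id", "") or "").strip()
        if not venue_id:
            raise ValueError(f"review row {i}: venue_id is required")
        d = _parse_date(row.get("review_date", ""), context=f"review row {i}")
        records.append(ReviewRecord(venue_id=venue_id, review_date=d))
    records.sort(key=lambda r: (r.venue_id, r.review_date))
    if known_venue_ids is not None:
        known = set(known_venue_ids)
        orphans = sum(1 for r in records if r.venue_id not in known)
        if orphans:
            logger.warning("%d reviews reference unknown venues (retained)", orphans)
    return records


def write_reviews(reviews: Sequence[ReviewRecord], path: str | Path, fmt: str = "csv") -> None:
    rows = [
        {"venue_id": r.venue_id, "review_date": r.review_date.isoformat()}
        for r in sorted(reviews, key=lambda r: (r.venue_id, r.review_date))
    ]
    _write_rows(rows, path, fmt, REVIEW_COLUMNS)


# ---------------------------------------------------------------------------
# ground-truth table
# ---------------------------------------------------------------------------


def read_ground_truth(path: str | Path, fmt: str = "csv") -> list[GroundTruthRecord]:
    records = []
    for i, row in enumerate(_read_rows(path, fmt), start=1):
        venue_id = str(row.get("venue_id", "") or "").strip()
        if not venue_id:
            raise ValueError(f"ground-truth row {i}: venue_id is required")
        raw_date = str(row.get("verified_opening_date", "") or "").strip()
        opening = _parse_date(raw_date, context=f"ground-truth row {i}") if raw_date else None
        status = str(row.get("verified_status", "") or "").strip() or None
        try:
            records.append(
                GroundTruthRecord(
                    venue_id=venue_id,
                    verified_opening_date=opening,
                    verified_status=status,
                    source_note=str(row.get("source_note", "") or ""),
                )
            )
        except ValueError as exc:
            raise ValueError(f"ground-truth row {i}: {exc}") from exc
    return records


def write_ground_truth(
    truth: Sequence[GroundTruthRecord], path: str | Path, fmt: str = "csv"
) -> None:
    rows = [
        {
            "venue_id": t.venue_id,
            "verified_opening_date": t.verified_opening_date.isoformat()
            if t.verified_opening_date
            else "",
            "verified_status": t.verified_status or "",
            "source_note": t.source_note,
        }
        for t in truth
    ]
    _write_rows(rows, path, fmt, TRUTH_COLUMNS)
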