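"""Opening-date estimation from first reviews.

The model: for venues whose opening date could be verified externally,
measure the calendar-month lag between opening and first review, average
it per opening year (the *correction table*), then predict every venue's
opening date as its first-review date minus the applicable year's mean
lag.  Early platform years have long, noisy lags, so predictions whose
first review predates a reliability cutoff year (default 2010) are marked
``pre-cutoff``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from dateutil.relativedelta import relativedelta

from .core_data import (
    GroundTruthRecord,
    ReviewRecord,
    months_between,
    round_half_up,
)

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_YEAR = 2010
DEFAULT_PLATFORM_LAUNCH = date(2004, 10, 1)


def first_review(venue_id: str, reviews: Sequence[ReviewRecord]) -> Optional[date]:
    """Earliest review date for the venue, or None if unreviewed."""
    dates = [r.review_date for r in reviews if r.venue_id == venue_id]
    return min(dates) if dates else None


def first_review_map(reviews: Sequence[ReviewRecord]) -> dict[str, date]:
    """venue_id -> earliest review date, one pass."""
    out: dict[str, date] = {}
    for r in reviews:
        prev = out.get(r.venue_id)
        if prev is None or r.review_date < prev:
            out[r.venue_id] = r.review_date
    return out


def last_review_map(reviews: Sequence[ReviewRecord]) -> dict[str, date]:
    """venue_id -> latest review date, one pass."""
    out: dict[str, date] = {}
    for r in reviews:
        prev = out.get(r.venue_id)
        if prev is None or r.review_date > prev:
            out[r.venue_id] = r.review_date
    return out


@dataclass
class CorrectionTable:
    """Per-opening-year mean first-review lag, in calendar months.

    ``rows`` maps year -> (n_venues, mean_lag_months); the mean is None for
    years with no calibration venues.  Years between the first and last
    calibration year are all present, so gaps are explicit.
    """

    rows: dict[int, tuple[int, Optional[float]]] = field(default_factory=dict)
    cutoff_year: int = DEFAULT_CUTOFF_YEAR

    def years(self) -> list[int]:
        return sorted(self.rows)

    def n_calibration_venues(self) -> int:
        return sum(n for n, _ in self.rows.values())

    def mean_lag(self, year: int) -> Optional[float]:
        """Mean lag for ``year`` with fallback for missing years.

        Falls back to the nearest earlier year with a fitted mean (larger
        historical lags are the conservative choice); when no earlier year
        exists, the nearest later year is used.
        """
        if not self.rows:
            raise ValueError("empty correction table")
        if year in self.rows and self.rows[year][1] is not None:
            return self.rows[year][1]
        earlier = [y for y in self.rows if y < year and self.rows[y][1] is not None]
        if earlier:
            return self.rows[max(earlier)][1]
        later = [y for y in self.rows if y > year and self.rows[y][1] is not None]
        if later:
            return self.rows[min(later)][1]
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "year": y,
                    "n_venues": self.rows[y][0],
                    "mean_lag_months": "" if self.rows[y][1] is None else self.rows[y][1],
                }
                for y in self.years()
            ],
            columns=["year", "n_venues", "mean_lag_months"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cutoff_year: int = DEFAULT_CUTOFF_YEAR) -> "CorrectionTable":
        df = pd.read_csv(path, dtype={"year": int, "n_venues": int})
        rows: dict[int, tuple[int, Optional[float]]] = {}
        for _, r in df.iterrows():
            raw = r["mean_lag_months"]
            mean = None if pd.isna(raw) or raw == "" else float(raw)
            rows[int(r["year"])] = (int(r["n_venues"]), mean)
        return cls(rows=rows, cutoff_year=cutoff_year)


def fit_correction_table(
    ground_truth: Sequence[GroundTruthRecord],
    reviews: Sequence[ReviewRecord],
    cutoff_year: int = DEFAULT_CUTOFF_YEAR,
    platform_launch: date = DEFAULT_PLATFORM_LAUNCH,
) -> CorrectionTable:
    """Calibrate per-year mean lags from venues with verified openings.

    Only venues whose verified opening is on/after the platform launch are
    usable (pre-platform venues cannot have a meaningful first-review lag).
    Verified venues with no reviews are excluded with a warning.
    """
    firsts = first_review_map(reviews)
    lags_by_year: dict[int, list[int]] = {}
    skipped_unreviewed = 0
    for gt in ground_truth:
        if gt.verified_opening_date is None:
            continue
        if gt.verified_opening_date < platform_launch:
            continue
        fr = firsts.get(gt.venue_id)
        if fr is None:
            skipped_unreviewed += 1
            continue
        lags_by_year.setdefault(gt.verified_opening_date.year, []).append(
            months_between(gt.verified_opening_date, fr)
        )
    if skipped_unreviewed:
        logger.warning(
            "%d venues with verified openings have no reviews; excluded from calibration",
            skipped_unreviewed,
        )
    if not lags_by_year:
        raise ValueError("no usable calibration venues (verified opening + at least one review)")
    rows: dict[int, tuple[int, Optional[float]]] = {}
    for year in range(min(lags_by_year), max(lags_by_year) + 1):
        lags = lags_by_year.get(year, [])
        rows[year] = (len(lags), float(pd.Series(lags).mean()) if lags else None)
    return CorrectionTable(rows=rows, cutoff_year=cutoff_year)


@dataclass(frozen=True)
class OpeningEstimate:
    """Predicted opening for one venue.

    ``confidence`` is ``"reliable"`` when the first review falls in or
    after the table's cutoff year, else ``"pre-cutoff"``.
    """

    venue_id: str
    first_review_date: date
    predicted_opening_date: date
    predicted_opening_year: int
    confidence: str

    def __post_init__(self) -> None:
        if self.predicted_opening_date > self.first_review_date:
            raise ValueError("predicted opening must not postdate the first review")


def predict_opening(
    first_review_date: date,
    table: CorrectionTable,
    venue_id: str = "",
) -> OpeningEstimate:
    """First-review date minus the applicable year's mean lag.

    The correction factor is keyed by the first-review year (the true
    opening year is unknown at prediction time) and rounded half-up to
    whole months before subtraction.
    """
    if not table.rows:
        raise ValueError("empty correction table")
    factor = table.mean_lag(first_review_date.year)
    if factor is None:
        raise ValueError("correction table has no fitted year")
    k = int(round_half_up(factor))
    predicted = first_review_date - relativedelta(months=k)
    confidence = "reliable" if first_review_date.year >= table.cutoff_year else "pre-cutoff"
    return OpeningEstimate(
        venue_id=venue_id,
        first_review_date=first_review_date,
        predicted_opening_date=predicted,
        predicted_opening_year=predicted.year,
        confidence=confidence,
    )


def predict_openings(
    reviews: Sequence[ReviewRecord],
    table: CorrectionTable,
) -> list[OpeningEstimate]:
    """One estimate per venue with at least one review, sorted by id."""
    firsts = first_review_map(reviews)
    return [predict_opening(fr, table, venue_id=vid) for vid, fr in sorted(firsts.items())]


def yearly_opening_histogram(
    estimates: Sequence[OpeningEstimate],
    min_year: Optional[int] = None,
) -> dict[str, int]:
    """Estimated openings per year; years before ``min_year`` pooled as "pre".

    Keys are year strings (plus "pre"); values sum to ``len(estimates)``.
    """
    counts: dict[str, int] = {}
    for est in estimates:
        y = est.predicted_opening_year
        key = "pre" if (min_year is not None and y < min_year) else str(y)
        counts[key] = counts.get(key, 0) + 1
    ordered: dict[str, int] = {}
    if "pre" in counts:
        ordered["pre"] = counts["pre"]
    for key in sorted(k for k in counts if k != "pre"):
        ordered[key] = counts[key]
    return ordered


def share_opened_since(histogram: Mapping[str, int], year: int, ndigits: int = 0) -> float:
    """Percent of venues estimated to have opened in ``year`` or later."""
    total = sum(histogram.values())
    recent = sum(c for k, c in histogram.items() if k != "pre" and int(k) >= year)
    return round_half_up(100.0 * recent / total, ndigits)


def estimates_frame(estimates: Sequence[OpeningEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "venue_id": e.venue_id,
                "first_review_date": e.first_review_date.isoformat(),
                "predicted_opening_date": e.predicted_opening_date.isoformat(),
                "predicted_opening_year": e.predicted_opening_year,
                "confidence": e.confidence,
            }
            for e in estimates
        ],
        columns=[
            "venue_id",
            "first_review_date",
            "predicted_opening_date",
            "predicted_opening_year",
            "confidence",
        ],
    )
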