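"""Monthly review-volume series and growth summaries.

Review counts are bucketed by calendar month into a contiguous series per
category; a control category (with slower growth) normalises for overall
platform expansion when comparing fold-changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import MonthKey, ReviewRecord, VenueRecord, round_half_up

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MonthlySeries:
    """Per-calendar-month review counts over a contiguous month range."""

    category: str
    start: Optional[MonthKey]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if (self.start is None) != (len(self.counts) == 0):
            raise ValueError("empty series must have no start month")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end(self) -> Optional[MonthKey]:
        """Last month in the series (inclusive)."""
        if self.start is None:
            return None
        return self.start.shift(len(self.counts) - 1)

    def month_keys(self) -> list[MonthKey]:
        return [self.start.shift(i) for i in range(len(self.counts))] if self.start else []

    def count_at(self, mk: MonthKey) -> int:
        if self.start is None or not self.start <= mk <= self.end:
            raise KeyError(f"{mk} outside series range")
        return self.counts[mk - self.start]

    def cumulative_through(self, mk: MonthKey) -> int:
        """Total reviews in all months up to and including ``mk``."""
        if self.start is None:
            return 0
        if mk < self.start:
            return 0
        idx = min(mk - self.start, len(self.counts) - 1)
        return int(np.cumsum(self.counts)[idx])

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": mk.year, "month": mk.month, "count": c, "cumulative": cum}
            for mk, c, cum in zip(
                self.month_keys(), self.counts, np.cumsum(self.counts) if self.counts else []
            )
        ]
        return pd.DataFrame(rows, columns=["year", "month", "count", "cumulative"])


def monthly_counts(
    reviews: Sequence[ReviewRecord],
    category: Optional[str] = None,
    venues: Optional[Sequence[VenueRecord]] = None,
    span: Optional[tuple[MonthKey, MonthKey]] = None,
) -> MonthlySeries:
    """Bucket reviews into calendar months.

    With ``category`` and ``venues`` given, only reviews of venues tagged
    with that category are counted.  The series spans from the first to
    the last review month (or the explicit ``span``), with zero-count
    months present.
    """
    if category is not None:
        if venues is None:
            raise ValueError("category filtering requires the venue table")
        member = {v.venue_id for v in venues if category in v.categories}
        reviews = [r for r in reviews if r.venue_id in member]
    months = [MonthKey.from_date(r.review_date) for r in reviews]
    if span is not None:
        start, end = span
    elif months:
        start, end = min(months), max(months)
    else:
        return MonthlySeries(category=category or "", start=None, counts=())
    counts = [0] * (end - start + 1)
    for mk in months:
        if start <= mk <= end:
            counts[mk - start] += 1
    return MonthlySeries(category=category or "", start=start, counts=tuple(counts))


def window_mean(series: MonthlySeries, start: MonthKey, end: MonthKey) -> float:
    """Mean reviews per month over the half-open window [start, end).

    One decimal, half-up.  The window must lie inside the series range.
    """
    if series.start is None:
        raise ValueError("empty series")
    if not start < end:
        raise ValueError("window start must precede end")
    if start < series.start or end.shift(-1) > series.end:
        raise ValueError(
            f"window [{start}, {end}) outside series range [{series.start}, {series.end}]"
        )
    total = sum(series.count_at(start.shift(i)) for i in range(end - start))
    return round_half_up(total / (end - start), 1)


def cumulative_fold_change(
    series: MonthlySeries, t0: MonthKey, t1: MonthKey
) -> Optional[float]:
    """Cumulative reviews through t1 over cumulative through t0, one decimal.

    None (with a warning) when the baseline cumulative count is zero.
    """
    base = series.cumulative_through(t0)
    if base == 0:
        logger.warning("cumulative count through %s is zero; fold-change undefined", t0)
        return None
    return round_half_up(series.cumulative_through(t1) / base, 1)


def monthly_fold_change(series: MonthlySeries, m0: MonthKey, m1: MonthKey) -> Optional[float]:
    """count(m1) / count(m0), one decimal; None when count(m0) is zero."""
    base = series.count_at(m0)
    if base == 0:
        logger.warning("count in %s is zero; fold-change undefined", m0)
        return None
    return round_half_up(series.count_at(m1) / base, 1)
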