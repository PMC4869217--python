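"""Synthetic review-platform datasets with known ground truth.

The generator emulates the statistical structure a review-recency
surveillance pipeline assumes:

* venue openings arrive Poisson per calendar year, with a year-varying
  rate (the "new venues per year" curve);
* each venue may close: a per-month Bernoulli hazard, i.e. a geometric
  months-to-closure;
* reviews arrive as a month-discretised nonhomogeneous Poisson process:
  in month *m* an active venue receives Poisson(base_rate x adoption(m))
  reviews, where adoption(m) is a logistic curve in calendar time that is
  0 before the platform launched — early venues therefore wait a long
  time for their first review, recent ones are reviewed almost at once;
* the platform's crowd-sourced closed-flag fires with probability
  ``flag_sensitivity`` on truly closed venues and *never* on open ones
  (perfect specificity by construction — downstream evaluation has to
  rediscover this);
* a verified opening date is available per venue with a probability that
  may depend on the opening year, emulating the recency bias of manual
  verification;
* a second "control" category (think wine bars vs hookah bars) shares the
  platform adoption curve but has its own opening-rate and review-rate
  parameters, so its review volume grows more slowly.

All randomness flows from a single integer seed; the same seed reproduces
the dataset byte for byte.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    GroundTruthRecord,
    MonthKey,
    ReviewRecord,
    VenueRecord,
    month_range,
)

logger = logging.getLogger(__name__)

#: Average month length in days, used to put dates on a fractional-month axis.
DAYS_PER_MONTH = 30.4375


def _ny_like_opening_rates() -> dict[int, float]:
    # Steep rise after 2009; expected ~140 venues over 2004-2014.
    return {
        2004: 2, 2005: 2, 2006: 3, 2007: 3, 2008: 4,
        2009: 8, 2010: 12, 2011: 16, 2012: 24, 2013: 30, 2014: 36,
    }


def _ny_like_verification_probs() -> dict[int, float]:
    # Manual verification favours recently opened venues.
    probs = {y: 0.12 for y in range(2004, 2009)}
    probs[2009] = 0.2
    probs.update({y: 0.35 for y in range(2010, 2015)})
    return probs


def _ny_like_control_rates() -> dict[int, float]:
    return {y: 10 for y in range(2005, 2015)}


def _ny_like_zip_weights() -> dict[str, float]:
    return {
        # Astoria, Queens
        "11103": 0.12, "11106": 0.06, "11102": 0.04, "11105": 0.03,
        # Lower East Side, Manhattan
        "10002": 0.07, "10003": 0.06, "10009": 0.04,
        # other Manhattan
        "10012": 0.03, "10016": 0.03, "10019": 0.03, "10036": 0.03,
        # Brooklyn
        "11211": 0.05, "11215": 0.04, "11223": 0.04, "11235": 0.03,
        # other Queens
        "11372": 0.05, "11354": 0.04, "11432": 0.03,
        # Bronx / Staten Island
        "10451": 0.04, "10458": 0.03, "10301": 0.03,
        # upstate
        "14201": 0.03, "12203": 0.02, "13210": 0.02, "10801": 0.01,
    }


_ATTRIBUTE_PROBS = {
    # (P(yes | known), P(known))
    "credit_cards": (0.85, 0.95),
    "alcohol": (0.50, 0.90),
    "wifi": (0.60, 0.85),
    "trendy": (0.15, 0.90),
}


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Defaults are the "ny-like" preset: a desk-scale mimic of a state-wide
    hookah-bar extract — openings rising steeply after 2009 to ~140 venues,
    platform launch October 2004, snapshot 2014-10-28, closed-flag
    sensitivity 0.77 — not a reproduction of any real data.
    """

    seed: int = 0
    year_range: tuple[int, int] = (2004, 2014)
    opening_rate_per_year: Mapping[int, float] = field(default_factory=_ny_like_opening_rates)
    closure_hazard_per_month: float = 0.006
    platform_launch: date = date(2004, 10, 1)
    adoption_midpoint: date = date(2010, 6, 15)
    adoption_steepness: float = 0.06  # per month
    base_review_rate: float = 1.2  # reviews per venue-month at full adoption
    flag_sensitivity: float = 0.77
    verification_prob_by_year: Mapping[int, float] = field(
        default_factory=_ny_like_verification_probs
    )
    category: str = "hookah bars"
    control_category: Optional[str] = "wine bars"
    control_opening_rate_per_year: Mapping[int, float] = field(
        default_factory=_ny_like_control_rates
    )
    control_review_rate: float = 1.0
    snapshot: date = date(2014, 10, 28)
    zip_weights: Mapping[str, float] = field(default_factory=_ny_like_zip_weights)

    def validate(self) -> None:
        probs = [self.closure_hazard_per_month, self.flag_sensitivity]
        probs += list(self.verification_prob_by_year.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        rates = list(self.opening_rate_per_year.values()) + [self.base_review_rate]
        if self.control_category is not None:
            rates += list(self.control_opening_rate_per_year.values())
            rates.append(self.control_review_rate)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be nonnegative")
        if abs(sum(self.zip_weights.values()) - 1.0) > 1e-9:
            raise ValueError("zip_weights must sum to 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (first, last) with first <= last")


def ny_like_config(seed: int = 0) -> SimConfig:
    """The default "ny-like" preset with the given seed."""
    return SimConfig(seed=seed)


@dataclass(frozen=True)
class SyntheticTruthRecord:
    """The simulator's private knowledge about one venue."""

    venue_id: str
    true_opening_date: date
    true_closure_date: Optional[date]  # None = still open at snapshot
    category: str
    zip: str

    @property
    def closed(self) -> bool:
        return self.true_closure_date is not None


def truth_frame(truth: Sequence[SyntheticTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "venue_id": t.venue_id,
                "true_opening_date": t.true_opening_date.isoformat(),
                "true_closure_date": t.true_closure_date.isoformat()
                if t.true_closure_date
                else "",
                "category": t.category,
                "zip": t.zip,
            }
            for t in truth
        ],
        columns=["venue_id", "true_opening_date", "true_closure_date", "category", "zip"],
    )


# ---------------------------------------------------------------------------
# adoption curve and month-rate schedule
# ---------------------------------------------------------------------------


def adoption_factor(t: date, config: SimConfig) -> float:
    """Platform adoption in [0, 1] at calendar date ``t``.

    Zero before the platform launch; logistic in (fractional) months since
    the adoption midpoint afterwards.  Nondecreasing in ``t``.
    """
    if t < config.platform_launch:
        return 0.0
    m = (t - config.adoption_midpoint).days / DAYS_PER_MONTH
    return 1.0 / (1.0 + math.exp(-config.adoption_steepness * m))


def _month_rate_schedule(
    opening: date,
    end: date,
    base_rate: float,
    config: SimConfig,
) -> tuple[list[MonthKey], np.ndarray, list[tuple[date, date]]]:
    """Expected review counts per calendar month for one venue.

    Months run from the opening month through the end month (closure or
    snapshot).  The rate in each month is base_rate x adoption(mid-month),
    prorated by the fraction of the month the venue was actually exposed
    (after opening, before end, after platform launch).  Also returns the
    admissible [start, end] date window of each month for placing reviews.
    """
    months: list[MonthKey] = []
    rates: list[float] = []
    windows: list[tuple[date, date]] = []
    for mk in month_range(MonthKey.from_date(opening), MonthKey.from_date(end)):
        w_start = max(mk.first_day(), opening, config.platform_launch)
        w_end = min(mk.last_day(), end)
        months.append(mk)
        windows.append((w_start, w_end))
        if w_end < w_start:
            rates.append(0.0)
            continue
        exposure = ((w_end - w_start).days + 1) / mk.n_days()
        mid = date(mk.year, mk.month, 15)
        rates.append(base_rate * adoption_factor(mid, config) * exposure)
    return months, np.asarray(rates, dtype=float), windows


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _sample_opening(rng: np.random.Generator, year: int, snapshot: date) -> Optional[date]:
    """Uniform opening day within the year, restricted to <= snapshot."""
    start = date(year, 1, 1)
    end = min(date(year, 12, 31), snapshot)
    if end < start:
        return None
    offset = int(rng.integers(0, (date(year, 12, 31) - start).days + 1))
    opening = start + timedelta(days=offset)
    return opening if opening <= snapshot else None


def _sample_closure(
    rng: np.random.Generator, opening: date, hazard: float, snapshot: date
) -> Optional[date]:
    """First month in which the Bernoulli closure hazard fires.

    Geometric months-to-closure; closures past the snapshot are truncated
    to "still open".  Hazard 0 means no venue ever closes.
    """
    if hazard <= 0.0:
        return None
    k = int(rng.geometric(hazard))  # support 1, 2, ...
    closure = _add_months_clamped(opening, k)
    return closure if closure <= snapshot else None


def _add_months_clamped(d: date, months: int) -> date:
    mk = MonthKey.from_date(d).shift(months)
    return date(mk.year, mk.month, min(d.day, mk.n_days()))


def _generate_category(
    rng: np.random.Generator,
    config: SimConfig,
    category: str,
    opening_rates: Mapping[int, float],
    review_rate: float,
    id_prefix: str,
    with_attributes: bool,
) -> tuple[list[VenueRecord], list[ReviewRecord], list[GroundTruthRecord], list[SyntheticTruthRecord]]:
    venues: list[VenueRecord] = []
    reviews: list[ReviewRecord] = []
    truth: list[GroundTruthRecord] = []
    sim_truth: list[SyntheticTruthRecord] = []
    zips = sorted(config.zip_weights)
    zip_p = np.asarray([config.zip_weights[z] for z in zips], dtype=float)
    zip_p = zip_p / zip_p.sum()
    counter = 0
    y0, y1 = config.year_range
    for year in range(y0, y1 + 1):
        rate = float(opening_rates.get(year, 0.0))
        n_open = int(rng.poisson(rate)) if rate > 0 else 0
        for _ in range(n_open):
            opening = _sample_opening(rng, year, config.snapshot)
            if opening is None:
                continue
            counter += 1
            venue_id = f"{id_prefix}{counter:04d}"
            closure = _sample_closure(
                rng, opening, config.closure_hazard_per_month, config.snapshot
            )
            end = closure if closure is not None else config.snapshot
            zip_code = str(rng.choice(zips, p=zip_p))

            _, rates, windows = _month_rate_schedule(opening, end, review_rate, config)
            counts = rng.poisson(rates)
            for count, (w_start, w_end) in zip(counts, windows):
                if count == 0 or w_end < w_start:
                    continue
                span = (w_end - w_start).days + 1
                offsets = rng.integers(0, span, size=int(count))
                for off in sorted(int(o) for o in offsets):
                    reviews.append(ReviewRecord(venue_id, w_start + timedelta(days=off)))

            closed = closure is not None
            flag = bool(closed and rng.random() < config.flag_sensitivity)

            attributes: dict[str, bool] = {}
            if with_attributes:
                for attr, (p_yes, p_known) in _ATTRIBUTE_PROBS.items():
                    known = rng.random() < p_known
                    val = bool(rng.random() < p_yes)
                    if known:
                        attributes[attr] = val
            venues.append(
                VenueRecord(
                    venue_id=venue_id,
                    name=f"{category.rstrip('s').title()} {counter}",
                    address=f"{100 + counter} Example St, New York, NY {zip_code}",
                    city="New York",
                    state="NY",
                    zip=zip_code,
                    categories=frozenset({category}),
                    platform_closed_flag=flag,
                    attributes=attributes,
                )
            )
            verify_p = float(config.verification_prob_by_year.get(year, 0.0))
            verified_opening = opening if rng.random() < verify_p else None
            truth.append(
                GroundTruthRecord(
                    venue_id=venue_id,
                    verified_opening_date=verified_opening,
                    verified_status="closed" if closed else "open",
                    source_note="synthetic",
                )
            )
            sim_truth.append(
                SyntheticTruthRecord(
                    venue_id=venue_id,
                    true_opening_date=opening,
                    true_closure_date=closure,
                    category=category,
                    zip=zip_code,
                )
            )
    return venues, reviews, truth, sim_truth


def generate_dataset(
    config: SimConfig,
) -> tuple[
    list[VenueRecord],
    list[ReviewRecord],
    list[GroundTruthRecord],
    list[SyntheticTruthRecord],
]:
    """Draw one complete synthetic dataset from ``config``.

    Returns (venues, reviews, ground_truth, synthetic_truth).  Reviews are
    sorted by (venue_id, review_date).  The ground-truth table carries a
    verified open/closed status for every venue and a verified opening date
    for the sampled verification subset; the synthetic-truth records hold
    the simulator's full private state for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = _generate_category(
        rng,
        config,
        config.category,
        config.opening_rate_per_year,
        config.base_review_rate,
        id_prefix="h",
        with_attributes=True,
    )
    venues, reviews, truth, sim_truth = (list(x) for x in out)
    if config.control_category is not None:
        c = _generate_category(
            rng,
            config,
            config.control_category,
            config.control_opening_rate_per_year,
            config.control_review_rate,
            id_prefix="w",
            with_attributes=False,
        )
        venues += c[0]
        reviews += c[1]
        truth += c[2]
        sim_truth += c[3]
    reviews.sort(key=lambda r: (r.venue_id, r.review_date))
    if not venues:
        logger.warning("degenerate simulation config: no venues generated")
    return venues, reviews, truth, sim_truth


# ---------------------------------------------------------------------------
# expected first-review lag (Monte-Carlo oracle for calibration recovery)
# ---------------------------------------------------------------------------


def expected_first_review_lag(
    opening_year: int,
    config: SimConfig,
    n_samples: int = 4000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Expected calendar-month lag from opening to first review.

    Monte-Carlo expectation under exactly the generator's mechanics —
    opening uniform in the year (truncated at the snapshot), geometric
    closure, month-discretised Poisson reviews under the adoption curve —
    conditional on the venue receiving at least one review by the snapshot
    (unreviewed venues never enter a calibration table).  NaN if no sample
    yields a review.
    """
    y0, y1 = config.year_range
    if not y0 <= opening_year <= y1:
        raise ValueError(f"opening_year {opening_year} outside year_range {config.year_range}")
    if rng is None:
        rng = np.random.default_rng((config.seed * 100003 + opening_year) % (2**31))
    lags: list[int] = []
    for _ in range(n_samples):
        opening = _sample_opening(rng, opening_year, config.snapshot)
        if opening is None:
            continue
        closure = _sample_closure(rng, opening, config.closure_hazard_per_month, config.snapshot)
        end = closure if closure is not None else config.snapshot
        _, rates, _ = _month_rate_schedule(opening, end, config.base_review_rate, config)
        if rates.size == 0:
            continue
        p_hit = -np.expm1(-rates)
        hits = rng.random(rates.size) < p_hit
        idx = np.flatnonzero(hits)
        if idx.size:
            lags.append(int(idx[0]))  # month j after the opening month = lag j
    return float(np.mean(lags)) if lags else float("nan")
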