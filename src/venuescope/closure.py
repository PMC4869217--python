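"""Open/closed classification from review recency, and its evaluation.

The recency rule: a venue is called *closed* when its most recent review
is at least ``threshold_months`` calendar months before the snapshot date
(default 6).  Venues with no reviews at all satisfy the rule vacuously and
are called closed (configurable).  The platform's own crowd-sourced
closed-flag serves as the baseline classifier.  Both are scored against
verified statuses in a 2x2 contingency table with *closed* as the positive
class.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core_data import (
    GroundTruthRecord,
    ReviewRecord,
    VenueRecord,
    months_between,
    round_half_up,
)
from .opening import last_review_map

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_MONTHS = 6


@dataclass(frozen=True)
class ClosureCall:
    """One venue's predicted status under one rule.

    ``months_since_last_review`` is None for venues with no reviews;
    ``rule`` is ``"recency-model"`` or ``"platform-flag"``.
    """

    venue_id: str
    months_since_last_review: Optional[int]
    predicted_status: str  # "open" | "closed"
    rule: str = "recency-model"


def recency_classify(
    reviews: Sequence[ReviewRecord],
    snapshot: date,
    threshold_months: int = DEFAULT_THRESHOLD_MONTHS,
    venue_ids: Optional[Sequence[str]] = None,
    reviewless_closed: bool = True,
) -> list[ClosureCall]:
    """Apply the recency rule at ``snapshot``.

    ``venue_ids`` extends the calls to venues with no reviews (predicted
    closed by default, or excluded when ``reviewless_closed`` is False).
    A review dated after the snapshot is a hard error.
    """
    lasts = last_review_map(reviews)
    for vid, last in lasts.items():
        if last > snapshot:
            raise ValueError(f"venue {vid}: review {last} postdates snapshot {snapshot}")
    ids = list(venue_ids) if venue_ids is not None else sorted(lasts)
    calls: list[ClosureCall] = []
    for vid in ids:
        last = lasts.get(vid)
        if last is None:
            if reviewless_closed:
                calls.append(ClosureCall(vid, None, "closed", "recency-model"))
            continue
        recency = months_between(last, snapshot)
        status = "closed" if recency >= threshold_months else "open"
        calls.append(ClosureCall(vid, recency, status, "recency-model"))
    return calls


def platform_flag_calls(venues: Sequence[VenueRecord]) -> list[ClosureCall]:
    """The baseline classifier: the platform's own closed-flag."""
    return [
        ClosureCall(
            v.venue_id,
            None,
            "closed" if v.platform_closed_flag else "open",
            "platform-flag",
        )
        for v in venues
    ]


def recency_stats(calls: Sequence[ClosureCall]) -> dict:
    """Distribution of months-since-last-review over reviewed venues.

    Returns min, max, mean (one decimal, half-up), median, and the mode
    with its venue count; mode ties break toward the smaller recency.
    """
    recencies = [c.months_since_last_review for c in calls if c.months_since_last_review is not None]
    if not recencies:
        raise ValueError("no calls with an observed recency")
    counts = Counter(recencies)
    best = max(counts.values())
    mode = min(r for r, n in counts.items() if n == best)
    return {
        "min": min(recencies),
        "max": max(recencies),
        "mean": round_half_up(sum(recencies) / len(recencies), 1),
        "median": statistics.median(recencies),
        "mode": mode,
        "mode_count": best,
        "n": len(recencies),
    }


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 truth-vs-prediction counts, "closed" as the positive class."""

    tp: int  # truly closed, predicted closed
    fn: int  # truly closed, predicted open
    fp: int  # truly open, predicted closed
    tn: int  # truly open, predicted open

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_truly_closed(self) -> int:
        return self.tp + self.fn

    @property
    def n_truly_open(self) -> int:
        return self.fp + self.tn

    def to_frame(self) -> pd.DataFrame:
        """Rows = truth, columns = prediction (the conventional layout)."""
        return pd.DataFrame(
            {
                "predicted_closed": [self.tp, self.fp],
                "predicted_open": [self.fn, self.tn],
            },
            index=pd.Index(["truly_closed", "truly_open"], name="truth"),
        )


def _truth_status_map(
    truth: Union[Sequence[GroundTruthRecord], Mapping[str, str]],
) -> dict[str, str]:
    if isinstance(truth, Mapping):
        return dict(truth)
    return {t.venue_id: t.verified_status for t in truth if t.verified_status is not None}


def evaluate(
    calls: Sequence[ClosureCall],
    truth: Union[Sequence[GroundTruthRecord], Mapping[str, str]],
) -> ContingencyTable:
    """Score predicted statuses against verified statuses.

    Venues without a verified status are excluded; their count is logged.
    """
    status = _truth_status_map(truth)
    tp = fn = fp = tn = 0
    excluded = 0
    for call in calls:
        true = status.get(call.venue_id)
        if true is None:
            excluded += 1
            continue
        pred_closed = call.predicted_status == "closed"
        if true == "closed":
            tp += pred_closed
            fn += not pred_closed
        else:
            fp += pred_closed
            tn += not pred_closed
    if excluded:
        logger.warning("%d venues lacked a verified status; excluded from evaluation", excluded)
    return ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)


def sensitivity(ct: ContingencyTable) -> Optional[float]:
    """Percent of truly closed venues called closed, one decimal half-up."""
    if ct.n_truly_closed == 0:
        logger.warning("no truly closed venues; sensitivity undefined")
        return None
    return round_half_up(100.0 * ct.tp / ct.n_truly_closed, 1)


def specificity(ct: ContingencyTable) -> Optional[float]:
    """Percent of truly open venues called open, one decimal half-up."""
    if ct.n_truly_open == 0:
        logger.warning("no truly open venues; specificity undefined")
        return None
    return round_half_up(100.0 * ct.tn / ct.n_truly_open, 1)


def threshold_sweep(
    reviews: Sequence[ReviewRecord],
    snapshot: date,
    truth: Union[Sequence[GroundTruthRecord], Mapping[str, str]],
    thresholds: Sequence[int],
    venue_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Sensitivity/specificity of the recency rule across thresholds.

    One row per threshold: threshold_months, tp, fn, fp, tn, sensitivity,
    specificity.  Sensitivity is nonincreasing and specificity
    nondecreasing in the threshold.
    """
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    rows = []
    for t in thresholds:
        calls = recency_classify(reviews, snapshot, threshold_months=t, venue_ids=venue_ids)
        ct = evaluate(calls, truth)
        rows.append(
            {
                "threshold_months": t,
                "tp": ct.tp,
                "fn": ct.fn,
                "fp": ct.fp,
                "tn": ct.tn,
                "sensitivity": sensitivity(ct),
                "specificity": specificity(ct),
            }
        )
    return pd.DataFrame(rows)


def calls_frame(calls: Sequence[ClosureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "venue_id": c.venue_id,
                "months_since_last_review": ""
                if c.months_since_last_review is None
                else c.months_since_last_review,
                "predicted_status": c.predicted_status,
                "rule": c.rule,
            }
            for c in calls
        ],
        columns=["venue_id", "months_since_last_review", "predicted_status", "rule"],
    )
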