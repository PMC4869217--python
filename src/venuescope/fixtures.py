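"""A small deterministic example dataset, built in code.

``structured_example_dataset`` returns a synthetic 144-venue single-city
extract whose truth/flag/recency structure is fully known by
construction:

* 31 venues are truly closed; 28 of them have gone >= 6 calendar months
  without a review, 3 were reviewed recently (they defeat the recency
  rule);
* 113 venues are truly open; 6 of them are stale (>= 6 months quiet) and
  107 were reviewed within the last 5 months, with 0 months the modal
  recency;
* the platform closed-flag marks 24 of the 31 closed venues and none of
  the open ones (perfect specificity, imperfect sensitivity);
* a calibration subset carries verified opening dates so the correction
  table can be fitted end to end.

Everything is arithmetic — no random number generator — so the dataset is
identical on every call and needs no packaged data files.
"""

from __future__ import annotations

from datetime import date

from .core_data import GroundTruthRecord, MonthKey, ReviewRecord, VenueRecord

SNAPSHOT = date(2014, 10, 28)
CATEGORY = "hookah bars"

# months since last review, per group (snapshot month = recency 0)
_CLOSED_STALE = [6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 18, 20, 22, 24, 26,
                 28, 30, 33, 36, 39, 42, 45, 48, 52, 56, 60, 65]
_CLOSED_FRESH = [1, 3, 5]
_OPEN_STALE = [6, 7, 8, 9, 11, 14]
_OPEN_FRESH = [0] * 45 + [1] * 25 + [2] * 15 + [3] * 10 + [4] * 7 + [5] * 5

# zip assignment: one dominant cluster plus a spread, mostly city zips
_ZIP_BLOCKS = (
    ["11103"] * 17 + ["10002"] * 12 + ["10003"] * 10 + ["11106"] * 8
    + ["11211"] * 8 + ["10009"] * 8
)
_ZIP_CYCLE = ["10012", "10016", "11215", "11372", "10451", "10301",
              "11354", "10019", "14201", "12203"]


def _zip_for(i: int) -> str:
    if i < len(_ZIP_BLOCKS):
        return _ZIP_BLOCKS[i]
    return _ZIP_CYCLE[(i - len(_ZIP_BLOCKS)) % len(_ZIP_CYCLE)]


def structured_example_dataset() -> tuple[
    list[VenueRecord], list[ReviewRecord], list[GroundTruthRecord]
]:
    """Build the 144-venue example extract (venues, reviews, ground truth)."""
    snapshot_month = MonthKey.from_date(SNAPSHOT)
    venues: list[VenueRecord] = []
    reviews: list[ReviewRecord] = []
    truth: list[GroundTruthRecord] = []

    groups = [
        ("closed", _CLOSED_STALE + _CLOSED_FRESH),
        ("open", _OPEN_STALE + _OPEN_FRESH),
    ]
    # flags: 22 stale + 2 fresh closed venues carry the platform flag = 24
    flagged_closed_idx = set(range(22)) | {28, 29}

    idx = 0
    for status, recencies in groups:
        for j, rec in enumerate(recencies):
            venue_id = f"{'c' if status == 'closed' else 'o'}{j + 1:03d}"
            zip_code = _zip_for(idx)
            last = MonthKey.from_index(snapshot_month.index - rec)
            last_review = date(last.year, last.month, 10)
            # first review 12-47 months before the last one, never pre-2005-08
            back = 12 + (idx * 7) % 36
            first = MonthKey.from_index(max(last.index - back, MonthKey(2005, 8).index))
            first_review = date(first.year, first.month, 20)
            if first_review > last_review:
                first_review = last_review
            reviews.append(ReviewRecord(venue_id, first_review))
            if first_review != last_review:
                reviews.append(ReviewRecord(venue_id, last_review))

            flag = status == "closed" and j in flagged_closed_idx
            venues.append(
                VenueRecord(
                    venue_id=venue_id,
                    name=f"Hookah Bar {venue_id.upper()}",
                    address=f"{100 + idx} Example St, New York, NY {zip_code}",
                    city="New York",
                    state="NY",
                    zip=zip_code,
                    categories=frozenset({CATEGORY}),
                    platform_closed_flag=flag,
                    attributes={
                        "credit_cards": idx % 6 != 5,   # ~5/6 accept cards
                        "trendy": idx % 7 == 0,
                        "wifi": idx % 3 != 0,
                    },
                )
            )
            # calibration subset: first 40 open venues get verified openings
            verified_opening = None
            if status == "open" and j < 40:
                lag = (1, 0, 2, 1, 3)[j % 5]  # months before the first review
                om = MonthKey.from_index(first.index - lag)
                verified_opening = date(om.year, om.month, 20)
            truth.append(
                GroundTruthRecord(
                    venue_id=venue_id,
                    verified_opening_date=verified_opening,
                    verified_status=status,
                    source_note="synthetic fixture",
                )
            )
            idx += 1
    reviews.sort(key=lambda r: (r.venue_id, r.review_date))
    return venues, reviews, truth
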