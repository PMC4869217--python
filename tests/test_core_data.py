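"""Records, calendar-month arithmetic, attribute summaries and table I/O."""

from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venuescope import core_data
from venuescope.core_data import (
    GroundTruthRecord,
    MonthKey,
    ReviewRecord,
    VenueRecord,
    months_between,
    percent,
    read_reviews,
    read_venues,
    round_half_up,
    snapshot_date,
    summarize_attributes,
    write_reviews,
    write_venues,
)

DATES = st.dates(min_value=date(1990, 1, 1), max_value=date(2030, 12, 31))


class TestMonthsBetween:
    @pytest.mark.parametrize(
        "earlier,later,expected",
        [
            (date(2014, 10, 1), date(2014, 10, 28), 0),   # same calendar month
            (date(2013, 1, 15), date(2014, 1, 2), 12),    # exact year
            (date(2014, 1, 31), date(2014, 2, 1), 1),     # day-of-month ignored
            (date(2014, 10, 28), date(2014, 1, 31), -9),  # negative allowed
        ],
    )
    def test_calendar_convention(self, earlier, later, expected):
        assert months_between(earlier, later) == expected

    @settings(derandomize=True, max_examples=200)
    @given(a=DATES, b=DATES, c=DATES)
    def test_additive_and_antisymmetric(self, a, b, c):
        assert months_between(a, b) + months_between(b, c) == months_between(a, c)
        assert months_between(a, b) == -months_between(b, a)
        assert months_between(a, a) == 0


class TestMonthKey:
    def test_ordering_and_difference(self):
        assert MonthKey(2014, 10) - MonthKey(2013, 10) == 12
        assert MonthKey(2014, 1) < MonthKey(2014, 2) < MonthKey(2015, 1)
        assert MonthKey(2014, 2).shift(-1) == MonthKey(2014, 1)

    @settings(derandomize=True, max_examples=100)
    @given(d=DATES, k=st.integers(-500, 500))
    def test_shift_roundtrip(self, d, k):
        mk = MonthKey.from_date(d)
        assert mk.shift(k).shift(-k) == mk
        assert mk.shift(k) - mk == k

    def test_rejects_bad_month(self):
        with pytest.raises(ValueError):
            MonthKey(2014, 13)


class TestSnapshotDate:
    def test_override_wins(self):
        reviews = [ReviewRecord("v1", date(2014, 9, 30))]
        assert snapshot_date(reviews, override=date(2014, 10, 28)) == date(2014, 10, 28)

    def test_defaults_to_latest_review(self):
        reviews = [
            ReviewRecord("v1", date(2014, 9, 30)),
            ReviewRecord("v2", date(2013, 2, 2)),
        ]
        assert snapshot_date(reviews) == date(2014, 9, 30)

    def test_empty_without_override_is_error(self):
        with pytest.raises(ValueError):
            snapshot_date([])


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(115, 137, 83.9), (20, 137, 14.6), (121, 137, 88.3), (0, 50, 0.0)],
    )
    def test_percent_half_up(self, num, den, expected):
        assert percent(num, den) == expected

    def test_ties_round_up(self):
        assert round_half_up(0.75, 1) == 0.8
        assert round_half_up(0.5) == 1.0
        assert round_half_up(2.345, 2) == 2.35


class TestSummarizeAttributes:
    def test_absent_counts_as_no_with_full_denominator(self):
        venues = [
            VenueRecord(f"v{i}", f"n{i}", attributes={"credit_cards": True})
            for i in range(115)
        ]
        venues += [VenueRecord(f"w{i}", f"n{i}", attributes={}) for i in range(22)]
        table = summarize_attributes(venues)
        row = table.set_index("attribute").loc["credit_cards"]
        assert (row["count_yes"], row["total"], row["percent"]) == (115, 137, 83.9)

    def test_bounds(self, ny_dataset):
        _, venues, _, _, _ = ny_dataset
        table = summarize_attributes(venues)
        assert ((table["percent"] >= 0) & (table["percent"] <= 100)).all()
        assert (table["count_yes"] <= table["total"]).all()


class TestVenueIO:
    def test_identity_ingest(self, tmp_path):
        p = tmp_path / "venues.csv"
        p.write_text(
            "venue_id,name,address,city,state,zip,categories,platform_closed_flag\n"
            "v1,Bar One,1 A St,NY,NY,10002,hookah bars,false\n"
            "v2,Bar Two,2 B St,NY,NY,10003,hookah bars|bars,true\n"
            "v3,Bar Three,3 C St,NY,NY,11103,,\n"
        )
        venues = read_venues(p)
        assert {v.venue_id for v in venues} == {"v1", "v2", "v3"}
        assert venues[1].categories == {"hookah bars", "bars"}
        assert venues[1].platform_closed_flag is True

    def test_malformed_zip_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "venues.csv"
        p.write_text("venue_id,name,zip\nv1,Bar,1103\n")
        with caplog.at_level("WARNING"):
            venues = read_venues(p)
        assert venues[0].zip is None
        assert any("zip" in r.message for r in caplog.records)

    def test_missing_name_is_hard_error_naming_row(self, tmp_path):
        p = tmp_path / "venues.csv"
        p.write_text("venue_id,name\nv1,Bar\nv2,\n")
        with pytest.raises(ValueError, match="row 2"):
            read_venues(p)

    def test_unknown_columns_become_attributes(self, tmp_path):
        p = tmp_path / "venues.csv"
        p.write_text("venue_id,name,wifi,serves_alcohol\nv1,Bar,true,\n")
        (v,) = read_venues(p)
        assert v.attributes == {"wifi": True}  # blank stays absent

    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_roundtrip_on_synthetic_set(self, fmt, tmp_path, ny_dataset):
        _, venues, _, _, _ = ny_dataset
        subset = venues[:50]
        p = tmp_path / f"venues.{fmt}"
        write_venues(subset, p, fmt)
        assert read_venues(p, fmt) == subset


class TestReviewIO:
    def test_sorted_ascending(self, tmp_path):
        p = tmp_path / "reviews.csv"
        p.write_text("venue_id,review_date\nv1,2014-10-28\nv1,2005-08-20\n")
        reviews = read_reviews(p)
        assert [r.review_date for r in reviews] == [date(2005, 8, 20), date(2014, 10, 28)]

    def test_unknown_venue_flagged(self, tmp_path, caplog):
        p = tmp_path / "reviews.csv"
        p.write_text("venue_id,review_date\nv1,2014-01-01\nghost,2014-01-02\n")
        with caplog.at_level("WARNING"):
            reviews = read_reviews(p, known_venue_ids=["v1"])
        assert len(reviews) == 2  # retained
        assert any("1 reviews reference unknown venues" in r.message for r in caplog.records)

    def test_unparseable_date_is_hard_error(self, tmp_path):
        p = tmp_path / "reviews.csv"
        p.write_text("venue_id,review_date\nv1,10/28/2014\n")
        with pytest.raises(ValueError, match="row 1"):
            read_reviews(p)

    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_roundtrip_multiset(self, fmt, tmp_path, ny_dataset):
        _, _, reviews, _, _ = ny_dataset
        subset = reviews[:500]
        p = tmp_path / f"reviews.{fmt}"
        write_reviews(subset, p, fmt)
        assert sorted(read_reviews(p, fmt)) == sorted(subset)


class TestGroundTruthRecord:
    def test_requires_some_verified_fact(self):
        with pytest.raises(ValueError):
            GroundTruthRecord(venue_id="v1")

    def test_roundtrip(self, tmp_path, ny_dataset):
        _, _, _, truth, _ = ny_dataset
        p = tmp_path / "truth.csv"
        core_data.write_ground_truth(truth, p)
        assert core_data.read_ground_truth(p) == list(truth)
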