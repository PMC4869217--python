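"""Correction-table calibration and opening-date prediction."""

from datetime import date

import pandas as pd
import pytest

from venuescope.core_data import GroundTruthRecord, ReviewRecord, months_between
from venuescope.opening import (
    CorrectionTable,
    first_review,
    first_review_map,
    fit_correction_table,
    predict_opening,
    predict_openings,
    share_opened_since,
    yearly_opening_histogram,
)


def _truth(venue_id, opening):
    return GroundTruthRecord(venue_id=venue_id, verified_opening_date=opening)


class TestFirstReview:
    def test_minimum(self):
        reviews = [
            ReviewRecord("v1", date(2012, 3, 5)),
            ReviewRecord("v1", date(2011, 7, 1)),
        ]
        assert first_review("v1", reviews) == date(2011, 7, 1)

    def test_absent_when_unreviewed(self):
        assert first_review("v1", [ReviewRecord("v2", date(2011, 7, 1))]) is None

    def test_matches_linear_scan_on_synthetic_venue(self, ny_dataset):
        _, _, reviews, _, _ = ny_dataset
        firsts = first_review_map(reviews)
        vid = max(firsts, key=lambda v: sum(r.venue_id == v for r in reviews))
        brute = min(r.review_date for r in reviews if r.venue_id == vid)
        assert first_review(vid, reviews) == brute == firsts[vid]


class TestFitCorrectionTable:
    def test_two_venue_year_mean(self):
        # lags of 34 and 35 months average to 34.5
        truth = [_truth("a", date(2006, 3, 10)), _truth("b", date(2006, 8, 1))]
        reviews = [
            ReviewRecord("a", date(2009, 1, 15)),   # 34 months
            ReviewRecord("b", date(2009, 7, 20)),   # 35 months
        ]
        table = fit_correction_table(truth, reviews)
        assert table.rows[2006] == (2, 34.5)

    def test_single_zero_lag(self):
        truth = [_truth("a", date(2014, 6, 1))]
        reviews = [ReviewRecord("a", date(2014, 6, 25))]
        table = fit_correction_table(truth, reviews)
        assert table.rows[2014] == (1, 0.0)

    def test_gap_years_present_with_absent_mean(self):
        truth = [_truth("a", date(2006, 1, 1)), _truth("b", date(2008, 1, 1))]
        reviews = [ReviewRecord("a", date(2006, 2, 1)), ReviewRecord("b", date(2008, 2, 1))]
        table = fit_correction_table(truth, reviews)
        assert table.rows[2007] == (0, None)

    def test_pre_platform_openings_excluded(self):
        truth = [_truth("old", date(2003, 1, 1)), _truth("new", date(2012, 1, 1))]
        reviews = [
            ReviewRecord("old", date(2006, 1, 1)),
            ReviewRecord("new", date(2012, 2, 1)),
        ]
        table = fit_correction_table(truth, reviews)
        assert list(table.rows) == [2012]

    def test_unreviewed_verified_venue_excluded_with_warning(self, caplog):
        truth = [_truth("a", date(2012, 1, 1)), _truth("b", date(2012, 2, 1))]
        reviews = [ReviewRecord("a", date(2012, 3, 1))]
        with caplog.at_level("WARNING"):
            table = fit_correction_table(truth, reviews)
        assert table.rows[2012][0] == 1
        assert any("no reviews" in r.message for r in caplog.records)

    def test_matches_groupby_oracle_on_synthetic_cohort(self, ny_dataset):
        cfg, _, reviews, truth, _ = ny_dataset
        table = fit_correction_table(truth, reviews)
        firsts = first_review_map(reviews)
        rows = [
            {
                "year": t.verified_opening_date.year,
                "lag": months_between(t.verified_opening_date, firsts[t.venue_id]),
            }
            for t in truth
            if t.verified_opening_date is not None
            and t.verified_opening_date >= cfg.platform_launch
            and t.venue_id in firsts
        ]
        oracle = pd.DataFrame(rows).groupby("year")["lag"].agg(["count", "mean"])
        for year, (n, mean) in table.rows.items():
            if n == 0:
                assert year not in oracle.index
            else:
                assert n == oracle.loc[year, "count"]
                assert mean == pytest.approx(oracle.loc[year, "mean"])

    def test_no_usable_venues_is_error(self):
        with pytest.raises(ValueError):
            fit_correction_table([_truth("a", date(2012, 1, 1))], [])


class TestPredictOpening:
    def test_fractional_factor_rounds_to_whole_month(self):
        table = CorrectionTable(rows={2014: (12, 0.75)})
        est = predict_opening(date(2014, 6, 15), table)
        assert est.predicted_opening_date == date(2014, 5, 15)
        assert est.confidence == "reliable"

    def test_zero_factor_is_identity(self):
        table = CorrectionTable(rows={2014: (1, 0.0)})
        est = predict_opening(date(2014, 6, 15), table)
        assert est.predicted_opening_date == date(2014, 6, 15)

    def test_pre_cutoff_confidence(self):
        table = CorrectionTable(rows={2008: (1, 22.0)}, cutoff_year=2010)
        est = predict_opening(date(2008, 3, 1), table)
        assert est.confidence == "pre-cutoff"

    def test_missing_year_falls_back_to_nearest_earlier(self):
        table = CorrectionTable(rows={2006: (2, 34.5), 2007: (0, None), 2008: (1, 22.0)})
        est = predict_opening(date(2007, 6, 1), table)
        # 2007 has no mean; 2006's 34.5 applies and rounds half-up to 35
        assert months_between(est.predicted_opening_date, date(2007, 6, 1)) == 35

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            predict_opening(date(2014, 1, 1), CorrectionTable(rows={}))

    def test_never_postdates_first_review(self, ny_dataset):
        _, _, reviews, truth, _ = ny_dataset
        table = fit_correction_table(truth, reviews)
        for est in predict_openings(reviews, table):
            assert est.predicted_opening_date <= est.first_review_date


class TestCorrectionTableIO:
    def test_csv_roundtrip_preserves_gap_years(self, tmp_path):
        table = CorrectionTable(rows={2006: (2, 34.5), 2007: (0, None), 2008: (1, 22.0)})
        p = tmp_path / "table.csv"
        table.to_csv(p)
        back = CorrectionTable.from_csv(p)
        assert back.rows == table.rows


class TestHistogram:
    def test_share_from_verified_cohort_structure(self):
        # per-year counts 2,0,1,2,6,3,11,6,12 (2006..2014): 40 of 43 in 2009+
        counts = {2006: 2, 2007: 0, 2008: 1, 2009: 2, 2010: 6,
                  2011: 3, 2012: 11, 2013: 6, 2014: 12}
        table = CorrectionTable(rows={y: (n, 1.0) for y, n in counts.items()})
        assert table.n_calibration_venues() == 43
        hist = {str(y): n for y, n in counts.items() if n}
        assert share_opened_since(hist, 2009) == 93.0

    def test_counts_sum_and_pre_pooling(self, ny_dataset):
        _, _, reviews, truth, _ = ny_dataset
        table = fit_correction_table(truth, reviews)
        estimates = predict_openings(reviews, table)
        hist = yearly_opening_histogram(estimates, min_year=2009)
        assert sum(hist.values()) == len(estimates)
        brute = sum(1 for e in estimates if e.predicted_opening_year < 2009)
        assert hist.get("pre", 0) == brute

    def test_single_year(self):
        table = CorrectionTable(rows={2014: (1, 0.0)})
        ests = [predict_opening(date(2014, m, 1), table) for m in range(1, 11)]
        hist = yearly_opening_histogram(ests)
        assert hist == {"2014": 10}


class TestPerfectCalibrationRegime:
    def test_saturated_platform_recovers_true_opening_years(self):
        # adoption ~ 1 and a high review rate: factors ~ 0 and predicted
        # years equal true years for every reviewed venue
        from venuescope.synthetic import SimConfig, generate_dataset

        cfg = SimConfig(
            seed=13,
            year_range=(2010, 2014),
            opening_rate_per_year={y: 30 for y in range(2010, 2015)},
            control_category=None,
            closure_hazard_per_month=0.0,
            adoption_midpoint=date(1990, 1, 1),
            adoption_steepness=1.0,
            base_review_rate=30.0,
            verification_prob_by_year={y: 1.0 for y in range(2010, 2015)},
        )
        _, reviews, truth, sim_truth = generate_dataset(cfg)
        table = fit_correction_table(truth, reviews)
        assert all(mean == pytest.approx(0.0, abs=0.05) for _, mean in table.rows.values() if mean is not None)
        true_year = {t.venue_id: t.true_opening_date.year for t in sim_truth}
        ests = predict_openings(reviews, table)
        mismatches = sum(e.predicted_opening_year != true_year[e.venue_id] for e in ests)
        assert mismatches == 0
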