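"""End-to-end orchestration: simulate/load -> fit -> predict -> classify ->
evaluate -> trends -> geo, with a reproducible report bundle.

``run_pipeline`` takes a :class:`RunConfig` pointing either at input
tables on disk or at a named simulation preset, runs every stage, writes
one file per artefact into the output directory, and returns (and writes)
a machine-readable summary.  With a fixed seed and config the bundle is
byte-identical across runs: nothing in it depends on wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

from . import closure, fixtures, geo, opening, synthetic, trends
from .core_data import (
    GroundTruthRecord,
    ReviewRecord,
    VenueRecord,
    MonthKey,
    read_ground_truth,
    read_reviews,
    read_venues,
    snapshot_date,
    summarize_attributes,
    write_ground_truth,
    write_reviews,
    write_venues,
)

logger = logging.getLogger(__name__)

PRESETS = ("ny-like", "tables-fixture")


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage runs)."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of (``preset``) or (``venues_path`` + ``reviews_path``)
    must be provided; ``truth_path`` is optional for real inputs.
    """

    outdir: Path
    preset: Optional[str] = None
    venues_path: Optional[Path] = None
    reviews_path: Optional[Path] = None
    truth_path: Optional[Path] = None
    seed: int = 0
    snapshot: Optional[date] = None
    cutoff_year: int = opening.DEFAULT_CUTOFF_YEAR
    threshold_months: int = closure.DEFAULT_THRESHOLD_MONTHS
    platform_launch: date = opening.DEFAULT_PLATFORM_LAUNCH
    min_histogram_year: int = 2006
    recent_since_year: int = 2009
    category: Optional[str] = None
    control_category: Optional[str] = None
    region_map_path: Optional[Path] = None

    def validate(self) -> None:
        has_files = self.venues_path is not None and self.reviews_path is not None
        if self.preset is None and not has_files:
            raise ConfigError("either a simulation preset or venue+review tables are required")
        if self.preset is not None and has_files:
            raise ConfigError("give a preset or input tables, not both")
        if self.preset is not None and self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; expected one of {PRESETS}")

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items()) if k != "outdir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(
    cfg: RunConfig, outdir: Path
) -> tuple[list[VenueRecord], list[ReviewRecord], list[GroundTruthRecord]]:
    if cfg.preset == "ny-like":
        sim = synthetic.ny_like_config(seed=cfg.seed)
        venues, reviews, truth, sim_truth = synthetic.generate_dataset(sim)
        synthetic.truth_frame(sim_truth).to_csv(outdir / "synthetic_truth.csv", index=False)
        if cfg.category is None:
            cfg.category = sim.category
        if cfg.control_category is None:
            cfg.control_category = sim.control_category
        if cfg.snapshot is None:
            cfg.snapshot = sim.snapshot
    elif cfg.preset == "tables-fixture":
        venues, reviews, truth = fixtures.structured_example_dataset()
        if cfg.category is None:
            cfg.category = fixtures.CATEGORY
        if cfg.snapshot is None:
            cfg.snapshot = fixtures.SNAPSHOT
    else:
        venues = read_venues(cfg.venues_path)
        reviews = read_reviews(cfg.reviews_path, known_venue_ids=[v.venue_id for v in venues])
        truth = read_ground_truth(cfg.truth_path) if cfg.truth_path else []
    write_venues(venues, outdir / "venues.csv")
    write_reviews(reviews, outdir / "reviews.csv")
    if truth:
        write_ground_truth(truth, outdir / "ground_truth.csv")
    return venues, reviews, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.outdir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "row_counts": {}}
    report_lines: list[str] = ["venuescope pipeline report", "=" * 30]

    def note(line: str) -> None:
        report_lines.append(line)
        logger.info(line)

    venues, reviews, truth = _load_inputs(cfg, outdir)
    summary["config_hash"] = cfg.config_hash()
    summary["row_counts"]["venues"] = len(venues)
    summary["row_counts"]["reviews"] = len(reviews)
    summary["row_counts"]["ground_truth"] = len(truth)
    note(f"inputs: {len(venues)} venues, {len(reviews)} reviews, "
         f"{len(truth)} ground-truth rows (venues.csv, reviews.csv, ground_truth.csv)")

    if cfg.category is not None:
        target_venues = [v for v in venues if cfg.category in v.categories]
        if not target_venues:
            target_venues = venues
    else:
        target_venues = venues
    target_ids = [v.venue_id for v in target_venues]
    target_reviews = [r for r in reviews if r.venue_id in set(target_ids)]
    summary["row_counts"]["target_venues"] = len(target_venues)

    snapshot = cfg.snapshot if cfg.snapshot is not None else snapshot_date(reviews)
    summary["snapshot"] = snapshot.isoformat()
    note(f"snapshot date: {snapshot}")

    # --- opening-date estimation -----------------------------------------
    truth_by_id = {t.venue_id: t for t in truth}
    target_truth = [truth_by_id[v] for v in target_ids if v in truth_by_id]
    n_verified = sum(1 for t in target_truth if t.verified_opening_date is not None)
    if n_verified:
        table = opening.fit_correction_table(
            target_truth,
            target_reviews,
            cutoff_year=cfg.cutoff_year,
            platform_launch=cfg.platform_launch,
        )
        table.to_csv(outdir / "correction_table.csv")
        summary["row_counts"]["calibration_venues"] = table.n_calibration_venues()
        note(f"correction table fitted on {table.n_calibration_venues()} verified venues "
             f"(correction_table.csv)")
        estimates = opening.predict_openings(target_reviews, table)
        opening.estimates_frame(estimates).to_csv(outdir / "opening_estimates.csv", index=False)
        hist = opening.yearly_opening_histogram(estimates, min_year=cfg.min_histogram_year)
        with open(outdir / "opening_histogram.json", "w", encoding="utf-8") as fh:
            json.dump(hist, fh, indent=1, sort_keys=False)
        share = opening.share_opened_since(hist, cfg.recent_since_year, ndigits=1)
        summary["opening"] = {
            "n_estimates": len(estimates),
            "histogram": hist,
            f"share_opened_{cfg.recent_since_year}_or_later_pct": share,
        }
        note(f"opening estimates for {len(estimates)} venues (opening_estimates.csv); "
             f"{share}% predicted to have opened in {cfg.recent_since_year} or later "
             f"(opening_histogram.json)")
    else:
        note("no verified opening dates: correction-table stage skipped")

    # --- closure classification and evaluation ---------------------------
    calls = closure.recency_classify(
        target_reviews, snapshot, threshold_months=cfg.threshold_months, venue_ids=target_ids
    )
    closure.calls_frame(calls).to_csv(outdir / "closure_calls.csv", index=False)
    stats = closure.recency_stats(calls)
    summary["recency_stats"] = stats
    note(f"recency rule ({cfg.threshold_months} months) on {len(calls)} venues "
         f"(closure_calls.csv); months-since-last-review min {stats['min']}, "
         f"max {stats['max']}, mean {stats['mean']}, median {stats['median']}, "
         f"mode {stats['mode']} ({stats['mode_count']} venues)")

    status_truth = {
        t.venue_id: t.verified_status for t in target_truth if t.verified_status is not None
    }
    if status_truth:
        ct_model = closure.evaluate(calls, status_truth)
        ct_model.to_frame().to_csv(outdir / "contingency_model.csv")
        flag_calls = closure.platform_flag_calls(target_venues)
        ct_flag = closure.evaluate(flag_calls, status_truth)
        ct_flag.to_frame().to_csv(outdir / "contingency_flag.csv")
        summary["evaluation"] = {
            "model": {
                "tp": ct_model.tp, "fn": ct_model.fn, "fp": ct_model.fp, "tn": ct_model.tn,
                "sensitivity_pct": closure.sensitivity(ct_model),
                "specificity_pct": closure.specificity(ct_model),
            },
            "platform_flag": {
                "tp": ct_flag.tp, "fn": ct_flag.fn, "fp": ct_flag.fp, "tn": ct_flag.tn,
                "sensitivity_pct": closure.sensitivity(ct_flag),
                "specificity_pct": closure.specificity(ct_flag),
            },
        }
        note(f"recency model vs truth: sensitivity "
             f"{summary['evaluation']['model']['sensitivity_pct']}%, specificity "
             f"{summary['evaluation']['model']['specificity_pct']}% (contingency_model.csv)")
        note(f"platform flag vs truth: sensitivity "
             f"{summary['evaluation']['platform_flag']['sensitivity_pct']}%, specificity "
             f"{summary['evaluation']['platform_flag']['specificity_pct']}% "
             f"(contingency_flag.csv)")
    else:
        note("no verified statuses: evaluation stage skipped")

    # --- trends -----------------------------------------------------------
    series = trends.monthly_counts(reviews, category=cfg.category, venues=venues) \
        if cfg.category else trends.monthly_counts(target_reviews)
    if len(series):
        series.to_frame().to_csv(outdir / "trend_target.csv", index=False)
        summary["row_counts"]["target_reviews"] = series.total
        trend_summary: dict = {"target_total_reviews": series.total}
        t1 = MonthKey.from_date(snapshot)
        t0 = MonthKey(t1.year - 6, t1.month)
        if series.start is not None and series.cumulative_through(t0) > 0:
            fold = trends.cumulative_fold_change(series, t0, t1)
            trend_summary[f"target_cumulative_fold_{t0}_to_{t1}"] = fold
            note(f"target reviews grew {fold}-fold cumulatively from {t0} to {t1} "
                 f"(trend_target.csv)")
        if cfg.control_category:
            control = trends.monthly_counts(reviews, category=cfg.control_category, venues=venues)
            if len(control):
                control.to_frame().to_csv(outdir / "trend_control.csv", index=False)
                trend_summary["control_total_reviews"] = control.total
                if control.cumulative_through(t0) > 0:
                    cfold = trends.cumulative_fold_change(control, t0, t1)
                    trend_summary[f"control_cumulative_fold_{t0}_to_{t1}"] = cfold
                    note(f"control reviews grew {cfold}-fold over the same window "
                         f"(trend_control.csv)")
        summary["trends"] = trend_summary

    # --- geography --------------------------------------------------------
    density = geo.zip_counts(target_venues)
    if density.counts:
        geo.export_density(density, outdir / "zip_density.csv", fmt="csv")
        geo.export_density(density, outdir / "zip_density.geojson", fmt="geojson")
        if cfg.region_map_path is not None:
            region_map = geo.RegionMap.from_csv(cfg.region_map_path)
        else:
            region_map = geo.default_nyc_boroughs(
                [z for z in density.counts if z != geo.UNKNOWN_ZIP]
            )
        rollup = geo.region_rollup(density, region_map)
        rollup.to_csv(outdir / "region_rollup.csv", index=False)
        city_zips = [z for zs in region_map.regions.values() for z in zs]
        city_share = density.region_share(city_zips)
        top_zip, top_count = max(density.counts.items(), key=lambda kv: (kv[1], kv[0]))
        summary["geo"] = {
            "n_zips": len(density.counts),
            "top_zip": top_zip,
            "top_zip_count": top_count,
            "city_share_pct": city_share,
        }
        note(f"zip density over {len(density.counts)} zips (zip_density.csv/.geojson); "
             f"largest cluster {top_count} venues in {top_zip}; {city_share}% of venues "
             f"inside the mapped regions (region_rollup.csv)")

    # --- attributes -------------------------------------------------------
    attrs = summarize_attributes(target_venues)
    if len(attrs):
        attrs.to_csv(outdir / "attribute_summary.csv", index=False)
        note("attribute summary written (attribute_summary.csv)")

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(report_lines) + "\n")
    return summary
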