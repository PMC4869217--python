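"""Zip-code density aggregation and exports for heat-map rendering.

Venues are counted per 5-digit zip; zips roll up into named regions
(boroughs, neighbourhoods) defined by an editable table rather than
hard-coded logic.  Exports are CSV or GeoJSON (RFC 7946) with zip-level
properties; polygon geometries are optional user-supplied inputs, so the
default export carries null geometry and remains fully testable offline.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core_data import VenueRecord, percent

logger = logging.getLogger(__name__)

UNKNOWN_ZIP = "unknown"
_ZIP_TOKEN = re.compile(r"(?<!\d)(\d{5})(?!\d)")


def extract_zip(address: Optional[str] = None, zip_field: Optional[str] = None) -> Optional[str]:
    """Best-effort zip: the explicit field if valid, else the last
    standalone 5-digit token in the address, else None."""
    if zip_field and re.fullmatch(r"\d{5}", zip_field):
        return zip_field
    if address:
        tokens = _ZIP_TOKEN.findall(address)
        if tokens:
            return tokens[-1]
    return None


@dataclass(frozen=True)
class ZipDensity:
    """Venue counts per zip; venues without a resolvable zip pool under
    ``"unknown"``."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts must sum to total")

    def region_share(self, zips: Sequence[str]) -> float:
        """Percent of all venues inside the given zip set (one decimal)."""
        inside = sum(self.counts.get(z, 0) for z in set(zips))
        return percent(inside, self.total) if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"zip": z, "count": c} for z, c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["zip", "count"])


def zip_counts(venues: Sequence[VenueRecord]) -> ZipDensity:
    """One count per distinct zip, extracted from the zip field or address."""
    counts: dict[str, int] = {}
    for v in venues:
        z = extract_zip(v.address, v.zip) or UNKNOWN_ZIP
        counts[z] = counts.get(z, 0) + 1
    return ZipDensity(counts=counts, total=len(venues))


@dataclass
class RegionMap:
    """Named zip groupings (boroughs, UHF-style neighbourhoods).

    ``regions`` maps region name -> set of zips.  Groupings may overlap
    (a neighbourhood inside a borough); rollups are computed per region
    independently, so use a disjoint map when a partition is wanted.
    """

    regions: dict[str, frozenset[str]] = field(default_factory=dict)

    def region_of(self, zip_code: str) -> Optional[str]:
        for name in sorted(self.regions):
            if zip_code in self.regions[name]:
                return name
        return None

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"region": name, "zip": z}
            for name in sorted(self.regions)
            for z in sorted(self.regions[name])
        ]
        pd.DataFrame(rows, columns=["region", "zip"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionMap":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        regions: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            regions.setdefault(row["region"], set()).add(row["zip"])
        return cls(regions={k: frozenset(v) for k, v in regions.items()})


#: NYC borough zip prefixes (3-digit).  100-102 Manhattan, 104 Bronx,
#: 103 Staten Island, 112 Brooklyn, 111/113/114/116 Queens.
_BOROUGH_PREFIXES = {
    "Manhattan": ("100", "101", "102"),
    "Bronx": ("104",),
    "Staten Island": ("103",),
    "Brooklyn": ("112",),
    "Queens": ("111", "113", "114", "116"),
}

#: Zips 10002/10003/10009 form the Lower East Side; the Astoria
#: neighbourhood is taken as the borough-consistent 111xx zip set (UHF
#: listings sometimes misprint it with Manhattan-style 100xx codes).
DEFAULT_NEIGHBORHOODS = {
    "Lower East Side": frozenset({"10002", "10003", "10009"}),
    "Astoria": frozenset({"11102", "11103", "11105", "11106"}),
}


def default_nyc_boroughs(observed_zips: Sequence[str]) -> RegionMap:
    """Borough map over the zips actually present, by standard prefix.

    Each zip lands in at most one borough; non-NYC zips are left out and
    will roll up under "other".
    """
    regions: dict[str, set[str]] = {name: set() for name in _BOROUGH_PREFIXES}
    for z in observed_zips:
        for name, prefixes in _BOROUGH_PREFIXES.items():
            if z.startswith(prefixes):
                regions[name].add(z)
                break
    return RegionMap(regions={k: frozenset(v) for k, v in regions.items() if v})


def default_nyc_neighborhoods() -> RegionMap:
    return RegionMap(regions=dict(DEFAULT_NEIGHBORHOODS))


def region_rollup(density: ZipDensity, region_map: RegionMap) -> pd.DataFrame:
    """Counts and shares per region; unmatched zips pool under "other".

    Columns: region, count, share_pct (one-decimal percent of the grand
    total).  With a non-overlapping region map the counts sum to the
    density total.
    """
    counts: dict[str, int] = {name: 0 for name in sorted(region_map.regions)}
    other = 0
    for z, c in density.counts.items():
        region = region_map.region_of(z) if z != UNKNOWN_ZIP else None
        if region is None:
            other += c
        else:
            counts[region] += c
    if other:
        counts["other"] = other
        logger.info("%d venues fall outside the region map (pooled as 'other')", other)
    rows = [
        {
            "region": name,
            "count": n,
            "share_pct": percent(n, density.total) if density.total else 0.0,
        }
        for name, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["region", "count", "share_pct"])


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export_density(
    density: ZipDensity,
    path: str | Path,
    fmt: str = "csv",
    geometries: Optional[Mapping[str, dict]] = None,
) -> None:
    """Write the density as CSV (zip, count) or a GeoJSON FeatureCollection.

    Rows/features are ordered by zip ascending for bit-stable output.
    ``geometries`` optionally maps zip -> GeoJSON geometry; absent zips get
    null geometry.
    """
    if not density.counts:
        raise ValueError("density is empty; nothing to export")
    if fmt == "csv":
        density.to_frame().to_csv(path, index=False)
    elif fmt == "geojson":
        features = [
            {
                "type": "Feature",
                "geometry": (geometries or {}).get(z),
                "properties": {"zip": z, "count": c},
            }
            for z, c in sorted(density.counts.items())
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected 'csv' or 'geojson')")


def import_density(path: str | Path, fmt: str = "csv") -> ZipDensity:
    """Read back an exported density (the inverse of ``export_density``)."""
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"zip": str, "count": int})
        counts = {str(r["zip"]): int(r["count"]) for _, r in df.iterrows()}
    elif fmt == "geojson":
        with open(path, encoding="utf-8") as fh:
            fc = json.load(fh)
        counts = {
            str(f["properties"]["zip"]): int(f["properties"]["count"])
            for f in fc["features"]
        }
    else:
        raise ValueError(f"unknown import format {fmt!r}")
    return ZipDensity(counts=counts, total=sum(counts.values()))
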