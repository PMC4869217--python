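"""Aggregate venues by zip code and roll up into boroughs/neighbourhoods.

The density table (zip -> venue count) is what a choropleth/heat-map
renderer consumes; the GeoJSON export carries the same counts as feature
properties (geometry optional, supplied by the user's boundary file).
"""

from pathlib import Path

from venuescope import generate_dataset, ny_like_config, region_rollup, zip_counts
from venuescope.geo import default_nyc_boroughs, default_nyc_neighborhoods, export_density

cfg = ny_like_config(seed=42)
venues, _, _, _ = generate_dataset(cfg)
target = [v for v in venues if cfg.category in v.categories]

density = zip_counts(target)
top = sorted(density.counts.items(), key=lambda kv: -kv[1])[:3]
print(f"{density.total} venues across {len(density.counts)} zips; "
      f"densest: {', '.join(f'{z} ({n})' for z, n in top)}")

boroughs = default_nyc_boroughs(list(density.counts))
print(region_rollup(density, boroughs).to_string(index=False))
city_zips = [z for zs in boroughs.regions.values() for z in zs]
print(f"-> {density.region_share(city_zips)}% of venues sit inside the five boroughs")

hoods = default_nyc_neighborhoods()
print(region_rollup(density, hoods).to_string(index=False))

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
export_density(density, out / "zip_density.geojson", fmt="geojson")
print(f"GeoJSON density written to {out / 'zip_density.geojson'}")
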