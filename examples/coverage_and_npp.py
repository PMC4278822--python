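"""Geographic annotation, coverage tables and TNPP weighting.

Annotates a seeded synthetic survey against rectangular region layers,
then summarises where sampling effort sits: the share of studies, sites
and samples per biome and per latitudinal band, compared with each
band's share of terrestrial area and of total net primary production
(TNPP) — the weighting used to judge how representative a collation is
of the productive land surface.
"""

from biocollate.fixtures import FixtureSpec, gen_checklist, gen_regions, gen_survey
from biocollate.geo import (
    annotate_sites,
    band_area_km2,
    coverage_table,
    latitudinal_band_classifier,
    latitudinal_coverage,
    total_npp,
)
from biocollate.model import assemble_database
from biocollate.taxonomy import resolve_database

spec = FixtureSpec(seed=7)
checklist, _ = gen_checklist(spec)
regions = gen_regions(spec)
bundles, _ = gen_survey(spec, checklist, regions)
db = assemble_database(bundles)
resolve_database(db, checklist)
annotate_sites(db, regions.ecoregions, regions.countries, regions.hotspots)

print("coverage by biome (% of studies / sites / samples):")
print(coverage_table(db, "biome").to_string(index=False))

print("\ncoverage by hotspot ('None' = outside all hotspots):")
print(coverage_table(db, "hotspot").to_string(index=False))

bands = latitudinal_coverage(db, band_width=5.0)
print("\ncoverage by 5-degree latitudinal band (study = median site latitude):")
print(bands.to_string(index=False))

# TNPP per band: mean daily NPP x days per month x terrestrial area.
tnpp = total_npp(regions.raster, latitudinal_band_classifier(5.0))
total = sum(tnpp.values())
lon_extent = regions.world_lon[1] - regions.world_lon[0]
area_total = sum(
    band_area_km2(lower, 5.0, lon_extent) for lower in range(-20, 20, 5)
)
print("\nband       % of TNPP   % of area")
for lower in range(-20, 20, 5):
    key = f"[{lower:g}, {lower + 5:g})"
    pct_npp = 100 * tnpp[key] / total
    pct_area = 100 * band_area_km2(lower, 5.0, lon_extent) / area_total
    print(f"{key:10s} {pct_npp:9.2f} {pct_area:11.2f}")
# Bands near the equator hold more TNPP than area: productivity peaks
# there, so equal-area sampling still under-samples productive land.
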