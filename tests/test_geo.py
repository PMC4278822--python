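"""Geographic matching, coverage statistics, cell areas and TNPP."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from biocollate.geo import (
    DAYS_IN_MONTH,
    LayerError,
    NPPRaster,
    RegionLayer,
    annotate_sites,
    band_of,
    coverage_table,
    latitudinal_band_classifier,
    latitudinal_coverage,
    match_nearest,
    match_within,
    study_latitude,
    total_npp,
)
from biocollate.model import SiteRecord
from biocollate.sphere import EARTH_RADIUS_KM, cell_area_km2, great_circle_m


@pytest.fixture()
def square_layer():
    return RegionLayer("test", [(box(0.0, 0.0, 10.0, 10.0), {"name": "inner"})])


class TestMatching:
    def test_point_inside_has_zero_distance(self, square_layer):
        attrs, d = match_nearest(square_layer, 5.0, 5.0)
        assert d == 0.0 and attrs["name"] == "inner"

    def test_containment_agrees_with_exact_matching(self, square_layer):
        attrs, d = match_nearest(square_layer, 5.0, 5.0)
        assert match_within(square_layer, 5.0, 5.0) == attrs

    def test_nearest_distance_close_to_haversine(self, square_layer):
        # 0.01 degrees due east of the eastern edge, at the equator
        attrs, d = match_nearest(square_layer, 0.0, 10.01)
        expected = great_circle_m(0.0, 10.01, 0.0, 10.0)
        assert d == pytest.approx(expected, rel=5e-3)
        assert d == pytest.approx(1112.0, rel=5e-3)

    def test_nearest_matches_brute_force_on_densified_boundary(self, square_layer):
        lat, lon = 3.7, 11.3
        geom = square_layer.features[0][0]
        n = 4000
        brute = math.inf
        coords = list(geom.exterior.coords)
        for (x1, y1), (x2, y2) in zip(coords, coords[1:]):
            for t in np.linspace(0, 1, n // len(coords)):
                brute = min(brute, great_circle_m(lat, lon, y1 + t * (y2 - y1),
                                                  x1 + t * (x2 - x1)))
        _, d = match_nearest(square_layer, lat, lon)
        assert d == pytest.approx(brute, rel=5e-3)

    def test_equidistant_tie_breaks_by_feature_order(self):
        layer = RegionLayer(
            "tie",
            [
                (box(0, 0, 1, 1), {"name": "first"}),
                (box(3, 0, 4, 1), {"name": "second"}),
            ],
        )
        attrs, d = match_nearest(layer, 0.5, 2.0)  # exactly between both
        assert attrs["name"] == "first"

    def test_boundary_point_counts_as_inside(self, square_layer):
        assert match_within(square_layer, 0.0, 5.0) is not None
        _, d = match_nearest(square_layer, 10.0, 10.0)
        assert d == 0.0

    def test_exact_matching_has_no_nearest_fallback(self, square_layer):
        assert match_within(square_layer, 5.0, 10.00001) is None  # ~1 m outside

    def test_empty_layer_is_a_configuration_error(self):
        layer = RegionLayer("empty", [])
        with pytest.raises(LayerError):
            match_nearest(layer, 0.0, 0.0)

    def test_antimeridian_crossing_rejected(self):
        with pytest.raises(LayerError, match="antimeridian"):
            RegionLayer("bad", [(box(170, 0, 190, 10), {"name": "x"})])


class TestAnnotation:
    def test_every_site_annotated_inland_distance_zero(self, annotated_db):
        assert annotated_db.annotated
        for site in annotated_db.sites:
            ann = annotated_db.annotations[site.key]
            assert ann.distances["country"] == 0.0
            assert ann.distances["ecoregion"] == 0.0
            assert ann.attributes["country"]
            assert ann.attributes["realm"]

    def test_reannotation_is_idempotent(self, annotated_db, regions):
        first = {k: (dict(a.attributes), dict(a.distances))
                 for k, a in annotated_db.annotations.items()}
        annotate_sites(annotated_db, regions.ecoregions, regions.countries, regions.hotspots)
        second = {k: (dict(a.attributes), dict(a.distances))
                  for k, a in annotated_db.annotations.items()}
        assert first == second

    def test_offshore_site_gets_nearest_country_with_distance(self, db, regions):
        db.sites[0].latitude = 21.0  # north of the fixture world: open sea
        db.sites[0].longitude = 10.0
        annotate_sites(db, regions.ecoregions, regions.countries, regions.hotspots)
        ann = db.annotations[db.sites[0].key]
        assert ann.distances["country"] > 0
        assert ann.attributes["country"] in regions.country_boxes


class TestStudyLatitude:
    def _sites(self, lats):
        return [SiteRecord(f"P{i}", "ST", latitude=lat, longitude=0.0)
                for i, lat in enumerate(lats)]

    def test_odd_count_is_middle_value(self):
        assert study_latitude(self._sites([0.0, 10.0, 20.0])) == 10.0

    def test_even_count_is_mean_of_central_two(self):
        assert study_latitude(self._sites([0.0, 10.0])) == 5.0

    def test_single_site_is_its_latitude(self):
        assert study_latitude(self._sites([-33.0])) == -33.0

    def test_no_coordinates_is_an_error(self):
        with pytest.raises(ValueError):
            study_latitude(self._sites([]))


class TestLatitudinalBands:
    def test_half_open_bands(self):
        assert band_of(0.0) == 0.0  # 0 belongs to [0, 5)
        assert band_of(-0.001) == -5.0
        assert band_of(4.999) == 0.0

    def test_top_band_closed(self):
        assert band_of(90.0) == 85.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            band_of(91.0)


class TestCoverage:
    def test_single_category_fixture_is_all_100(self, annotated_db):
        for site in annotated_db.sites:
            annotated_db.annotations[site.key].attributes["biome"] = "Only Biome"
        table = coverage_table(annotated_db, "biome")
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.percent_studies, row.percent_sites, row.percent_samples) == (100, 100, 100)

    def test_none_row_for_sites_outside_all_hotspots(self, annotated_db):
        table = coverage_table(annotated_db, "hotspot").set_index("category")
        assert "None" in table.index

    def test_columns_sum_to_100_over_a_partition(self, annotated_db):
        for attr in ("biome", "country", "ecoregion"):
            table = coverage_table(annotated_db, attr)
            assert table["percent_sites"].sum() == pytest.approx(100, abs=0.01)
            assert table["percent_samples"].sum() == pytest.approx(100, abs=0.01)
            # studies can span categories, so their column may exceed 100
            assert table["percent_studies"].sum() >= 100 - 0.01

    def test_coverage_permutation_invariant(self, annotated_db):
        t1 = coverage_table(annotated_db, "biome")
        annotated_db.sites = list(reversed(annotated_db.sites))
        t2 = coverage_table(annotated_db, "biome")
        assert t1.set_index("category").sort_index().equals(
            t2.set_index("category").sort_index()
        )

    def test_latitudinal_coverage_uses_study_median(self, annotated_db):
        table = latitudinal_coverage(annotated_db)
        assert table["percent_studies"].sum() == pytest.approx(100, abs=0.01)
        assert table["percent_sites"].sum() == pytest.approx(100, abs=0.01)


class TestCellArea:
    def test_band_ratio_follows_sine_differences(self):
        eq = cell_area_km2(0, 5, 360)
        polar = cell_area_km2(60, 65, 360)
        expected = (math.sin(math.radians(65)) - math.sin(math.radians(60))) / (
            math.sin(math.radians(5)) - math.sin(math.radians(0))
        )
        assert polar / eq == pytest.approx(expected, rel=1e-12)

    def test_sphere_area_conserved(self):
        total = sum(cell_area_km2(lat, lat + 5, 360) for lat in range(-90, 90, 5))
        assert total == pytest.approx(4 * math.pi * EARTH_RADIUS_KM**2, rel=1e-9)

    def test_zero_width_cell_is_zero(self):
        assert cell_area_km2(10, 10, 5) == 0.0


def _uniform_raster(value=1.0, nrows=4, ncols=4, cellsize=1.0):
    return NPPRaster(
        months=np.full((12, nrows, ncols), value),
        mask=np.ones((nrows, ncols)),
        xllcorner=0.0,
        yllcorner=0.0,
        cellsize=cellsize,
    )


class TestTNPP:
    def test_uniform_single_cell_closed_form(self):
        raster = _uniform_raster(value=1.0, nrows=1, ncols=1)
        out = total_npp(raster, lambda lat, lon: "all")
        # 1 g C m^-2 day^-1 x 365 days x cell area in m^2
        expected = 365.0 * raster.cell_area_m2(0)
        assert out["all"] == pytest.approx(expected, rel=1e-12)

    def test_all_missing_raster_contributes_zero(self):
        raster = _uniform_raster()
        raster.months[:] = np.nan
        out = total_npp(raster, lambda lat, lon: "all")
        assert out["all"] == 0.0

    def test_additive_over_disjoint_regions(self):
        raster = _uniform_raster(value=2.0)
        whole = total_npp(raster, lambda lat, lon: "all")["all"]
        split = total_npp(raster, lambda lat, lon: "west" if lon < 2 else "east")
        assert split["west"] + split["east"] == pytest.approx(whole, rel=1e-12)

    def test_linear_in_raster_values(self):
        r1 = _uniform_raster(value=1.0)
        r3 = _uniform_raster(value=3.0)
        v1 = total_npp(r1, lambda lat, lon: "all")["all"]
        v3 = total_npp(r3, lambda lat, lon: "all")["all"]
        assert v3 == pytest.approx(3 * v1, rel=1e-12)

    def test_mask_scales_contribution(self):
        raster = _uniform_raster()
        raster.mask[:] = 0.5
        half = total_npp(raster, lambda lat, lon: "all")["all"]
        raster.mask[:] = 1.0
        full = total_npp(raster, lambda lat, lon: "all")["all"]
        assert half == pytest.approx(full / 2, rel=1e-12)

    def test_band_classifier_partitions_cells(self, regions):
        out = total_npp(regions.raster, latitudinal_band_classifier(5.0))
        assert all(v > 0 for v in out.values())
        assert len(out) == 8  # 40 degrees of fixture latitude in 5-degree bands
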