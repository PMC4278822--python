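"""Geographic annotation and coverage statistics.

Sites are matched to attributed polygon layers: terrestrial ecoregions
(giving ecoregion, biome and biogeographic realm), country borders
(country, region, subregion) and biodiversity hotspots.  Global GIS
layers are coarse at local scales, so coastal and island sites can fall
slightly outside the relevant polygon: ecoregion and country matching
therefore falls back to the *nearest* polygon, recording the distance in
meters (zero for sites inside a polygon) so that non-zero distances can
be reviewed.  Hotspot matching is exact, with no nearest fallback.

Coverage statistics summarise where sampling effort sits: the percentage
of studies, sites and samples per category (biome, hotspot, country,
five-degree latitudinal band), compared against the category's share of
terrestrial area and of total net primary production (TNPP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, TYPE_CHECKING

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .sphere import EARTH_RADIUS_KM, cell_area_km2, great_circle_m

if TYPE_CHECKING:  # pragma: no cover
    from .model import SurveyDatabase, StudyRecord, SiteRecord


class LayerError(ValueError):
    """A region layer is missing, empty or unusable."""


@dataclass
class RegionLayer:
    """A named collection of attributed polygons in WGS84.

    Polygons crossing the antimeridian are rejected: longitudes must lie
    in [-180, 180] and each geometry must not span more than 180 degrees.
    """

    layer_name: str
    features: List[Tuple[BaseGeometry, Dict[str, str]]]

    def __post_init__(self) -> None:
        for i, (geom, attrs) in enumerate(self.features):
            if geom is None or geom.is_empty:
                raise LayerError(f"layer {self.layer_name!r}: feature {i} has no geometry")
            if not attrs:
                raise LayerError(f"layer {self.layer_name!r}: feature {i} has no attributes")
            minx, _, maxx, _ = geom.bounds
            if minx < -180 or maxx > 180 or (maxx - minx) > 180:
                raise LayerError(
                    f"layer {self.layer_name!r}: feature {i} crosses the antimeridian "
                    f"or has out-of-range longitudes; such geometries are unsupported"
                )

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class Annotation:
    """Per-site layer attributes and distances (meters; 0 when inside).
    The hotspot attribute is absent for sites outside every hotspot."""

    site_key: Tuple[str, str]
    attributes: Dict[str, str] = field(default_factory=dict)
    distances: Dict[str, float] = field(default_factory=dict)


def _boundary_distance_m(geom: BaseGeometry, lat: float, lon: float) -> float:
    """Great-circle distance from a point to a polygon boundary, taken as
    the minimum over boundary points sampled densely along the edges
    (plus the planar-nearest boundary point as a candidate)."""
    from shapely.ops import nearest_points

    point = Point(lon, lat)
    boundary = geom.boundary
    best = math.inf
    # planar nearest point is an excellent candidate at these scales
    nearest = nearest_points(boundary, point)[0]
    best = great_circle_m(lat, lon, nearest.y, nearest.x)
    densified = boundary.segmentize(0.02)  # ~2 km vertex spacing
    coords: List[Tuple[float, float]] = []
    if densified.geom_type == "LineString":
        coords = list(densified.coords)
    else:
        for part in getattr(densified, "geoms", []):
            coords.extend(part.coords)
    for x, y in coords:
        d = great_circle_m(lat, lon, y, x)
        if d < best:
            best = d
    return best


def match_nearest(layer: RegionLayer, lat: float, lon: float) -> Tuple[Dict[str, str], float]:
    """Match a point to the containing feature (distance 0) or, failing
    that, the nearest feature by boundary distance.  Boundary points
    count as inside.  Ties break deterministically in feature order."""
    if not layer.features:
        raise LayerError(f"layer {layer.layer_name!r} is empty")
    point = Point(lon, lat)
    for geom, attrs in layer.features:
        if geom.covers(point):
            return dict(attrs), 0.0
    best_attrs: Optional[Dict[str, str]] = None
    best = math.inf
    for geom, attrs in layer.features:
        d = _boundary_distance_m(geom, lat, lon)
        if d < best:
            best = d
            best_attrs = attrs
    return dict(best_attrs), best


def match_within(layer: RegionLayer, lat: float, lon: float) -> Optional[Dict[str, str]]:
    """Exact containment match (boundary counts as inside); None when the
    point is in no feature.  Used for hotspots, which have no nearest
    fallback."""
    if not layer.features:
        raise LayerError(f"layer {layer.layer_name!r} is empty")
    point = Point(lon, lat)
    for geom, attrs in layer.features:
        if geom.covers(point):
            return dict(attrs)
    return None


def annotate_sites(
    db: "SurveyDatabase",
    ecoregions: RegionLayer,
    countries: RegionLayer,
    hotspots: Optional[RegionLayer] = None,
) -> "SurveyDatabase":
    """Annotate every site with ecoregion/biome/realm and
    country/region/subregion (nearest-polygon with distances) and, when a
    hotspot layer is given, the containing hotspot (exact).  Idempotent:
    re-annotation replaces previous annotations."""
    if ecoregions is None or countries is None:
        raise LayerError("ecoregion and country layers are both mandatory")
    db.annotations = {}
    for site in db.sites:
        if site.latitude is None or site.longitude is None:
            raise LayerError(f"site {site.key} has no coordinates; validate first")
        ann = Annotation(site_key=site.key)
        eco_attrs, eco_d = match_nearest(ecoregions, site.latitude, site.longitude)
        ann.attributes.update(eco_attrs)
        ann.distances["ecoregion"] = eco_d
        c_attrs, c_d = match_nearest(countries, site.latitude, site.longitude)
        ann.attributes.update(c_attrs)
        ann.distances["country"] = c_d
        if hotspots is not None:
            h = match_within(hotspots, site.latitude, site.longitude)
            if h is not None:
                ann.attributes.update(h)
        db.annotations[site.key] = ann
    return db


# ---------------------------------------------------------------------------
# Coverage statistics


def study_latitude(sites: Sequence["SiteRecord"]) -> float:
    """A study's latitude: the median of its sites' latitudes (mean of
    the central two for even counts)."""
    lats = sorted(s.latitude for s in sites if s.latitude is not None)
    if not lats:
        raise ValueError("study has no sites with coordinates")
    n = len(lats)
    mid = n // 2
    if n % 2:
        return lats[mid]
    return (lats[mid - 1] + lats[mid]) / 2.0


def band_of(lat: float, band_width: float = 5.0) -> float:
    """Lower edge of the latitudinal band containing ``lat``.  Bands are
    half-open [lower, upper) except the top band, which is closed so that
    +90 belongs to the last band."""
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} out of range")
    if lat == 90.0:
        return 90.0 - band_width
    return -90.0 + band_width * math.floor((lat + 90.0) / band_width)


def _percent(counts: Mapping[str, float]) -> Dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


COVERAGE_COLUMNS = ["category", "percent_studies", "percent_sites", "percent_samples"]


def _coverage_frame(
    db: "SurveyDatabase", site_category: Callable[["SiteRecord"], str],
    study_category: Optional[Callable[["StudyRecord"], Sequence[str]]] = None,
) -> pd.DataFrame:
    """Shared machinery: per category, % of studies / sites / samples.

    By default a study contributes to every category any of its sites
    falls in (so multi-category studies count once per category, and the
    studies column is a percentage of the study total, not of category
    assignments)."""
    counts = db.measurement_counts()
    site_counts: Dict[str, int] = {}
    sample_counts: Dict[str, int] = {}
    study_cats: Dict[str, set] = {st.study_id: set() for st in db.studies}
    for site in db.sites:
        cat = site_category(site)
        site_counts[cat] = site_counts.get(cat, 0) + 1
        sample_counts[cat] = sample_counts.get(cat, 0) + counts[site.key]
        study_cats[site.study_id].add(cat)
    if study_category is not None:
        study_cats = {st.study_id: set(study_category(st)) for st in db.studies}
    n_studies = len(db.studies) or 1
    study_counts: Dict[str, int] = {}
    for cats in study_cats.values():
        for cat in cats:
            study_counts[cat] = study_counts.get(cat, 0) + 1
    categories = sorted(set(site_counts) | set(study_counts))
    pct_sites = _percent({c: site_counts.get(c, 0) for c in categories})
    pct_samples = _percent({c: sample_counts.get(c, 0) for c in categories})
    rows = [
        {
            "category": c,
            "percent_studies": 100.0 * study_counts.get(c, 0) / n_studies,
            "percent_sites": pct_sites[c],
            "percent_samples": pct_samples[c],
        }
        for c in categories
    ]
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)


def coverage_table(db: "SurveyDatabase", attribute: str) -> pd.DataFrame:
    """Coverage by an annotation attribute ("biome", "hotspot",
    "country", "realm", ...).  Sites lacking the attribute (e.g. outside
    every hotspot) fall in a "None" row.  Requires annotation."""
    if not db.annotated:
        raise ValueError("database not annotated: run annotate_sites() first")

    def cat(site: "SiteRecord") -> str:
        return db.annotations[site.key].attributes.get(attribute) or "None"

    return _coverage_frame(db, cat)


def latitudinal_coverage(db: "SurveyDatabase", band_width: float = 5.0) -> pd.DataFrame:
    """Coverage by latitudinal band: sites and samples by the band of the
    site's latitude, studies by the band of the study latitude (the
    median of its sites' latitudes).  The category column holds the
    band's lower edge."""
    by_study = {st.study_id: db.sites_of(st.study_id) for st in db.studies}

    def site_cat(site: "SiteRecord") -> str:
        return _band_label(band_of(site.latitude, band_width), band_width)

    def study_cat(study: "StudyRecord") -> Sequence[str]:
        return [_band_label(band_of(study_latitude(by_study[study.study_id]), band_width), band_width)]

    return _coverage_frame(db, site_cat, study_cat)


def _band_label(lower: float, band_width: float) -> str:
    return f"[{lower:g}, {lower + band_width:g})"


def band_area_km2(lower: float, band_width: float = 5.0, lon_extent_deg: float = 360.0) -> float:
    """Terrestrial-frame area of one latitudinal band (whole sphere by
    default; restrict ``lon_extent_deg`` for regional fixtures)."""
    return cell_area_km2(lower, lower + band_width, lon_extent_deg)


# ---------------------------------------------------------------------------
# NPP raster and TNPP

DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)  # non-leap year


@dataclass
class NPPRaster:
    """Twelve monthly grids of mean daily net primary productivity
    (g C m^-2 day^-1) plus a terrestrial-fraction mask, on a regular
    lat/lon grid.  Row 0 is the northernmost row (ESRI ASCII layout);
    NaN marks missing cells."""

    months: np.ndarray  # shape (12, nrows, ncols)
    mask: np.ndarray  # terrestrial fraction in [0, 1], shape (nrows, ncols)
    xllcorner: float
    yllcorner: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.months.shape[0] != 12:
            raise ValueError("NPP raster needs 12 monthly layers")
        if self.months.shape[1:] != self.mask.shape:
            raise ValueError("mask shape does not match monthly grids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.months) < 0:
                raise ValueError("negative NPP values")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.mask.shape

    def cell_center(self, row: int, col: int) -> Tuple[float, float]:
        nrows = self.mask.shape[0]
        lat = self.yllcorner + (nrows - 1 - row + 0.5) * self.cellsize
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        return lat, lon

    def cell_area_m2(self, row: int) -> float:
        nrows = self.mask.shape[0]
        south = self.yllcorner + (nrows - 1 - row) * self.cellsize
        return cell_area_km2(south, south + self.cellsize, self.cellsize) * 1e6


def total_npp(
    raster: NPPRaster,
    classifier: Callable[[float, float], Optional[str]],
) -> Dict[str, float]:
    """Total net primary production (g C yr^-1) per region.

    Each cell contributes, for every month, its mean daily value times
    the days in that month times its terrestrial area in m^2; the twelve
    monthly totals sum to the annual value (non-leap year).  ``classifier``
    maps a cell center (lat, lon) to a region key (None to skip the
    cell); missing cells contribute 0.
    """
    out: Dict[str, float] = {}
    nrows, ncols = raster.shape
    month_days = np.asarray(DAYS_IN_MONTH, dtype=float)
    for r in range(nrows):
        area = raster.cell_area_m2(r)
        for c in range(ncols):
            lat, lon = raster.cell_center(r, c)
            key = classifier(lat, lon)
            if key is None:
                continue
            vals = raster.months[:, r, c]
            filled = np.nan_to_num(vals, nan=0.0)
            annual = float(np.dot(filled, month_days)) * area * float(raster.mask[r, c])
            out[key] = out.get(key, 0.0) + annual
    return out


def latitudinal_band_classifier(band_width: float = 5.0) -> Callable[[float, float], str]:
    def classify(lat: float, lon: float) -> str:
        return _band_label(band_of(lat, band_width), band_width)

    return classify
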