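"""Relational model for site-by-species survey collations.

Data are organised into three levels.  A *Data Source* is a publication
(or report/thesis) contributing data.  A Source contains one or more
*Studies*; all diversity measurements within a Study were collected with
a single sampling method, so measurements are directly comparable within
but not among Studies.  A Study contains two or more *Sites* — sampled
locations with coordinates, land-use attributes and sampling dates — a
taxon list, and a site-by-taxon matrix of diversity measurements
(abundance, occurrence or species richness).

This module holds the record types, the blank-cell interpretation rule
for incoming matrices, the assembly of study bundles into a referentially
checked :class:`SurveyDatabase`, and the per-site summary extract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .siteattrs import DateInterval, LandUse, UseIntensity

MULTIPLE_COUNTRIES = "Multiple countries"

METRIC_TYPES = ("abundance", "occurrence", "species_richness")

PROVENANCE_KINDS = (
    "journal article",
    "unpublished",
    "internet database",
    "thesis",
    "report",
    "other",
)


class AssemblyError(ValueError):
    """A study bundle violated a structural invariant; the message names
    the offending record."""


@dataclass(frozen=True)
class PatchArea:
    """Tri-state habitat patch area.

    ``kind`` is ``"known"`` (with ``area_m2`` set), ``"unknown_large"``
    (the patch extends far beyond the sampled site; serialised as the
    sentinel -1 at the I/O layer only) or ``"unknown"``.
    """

    kind: str = "unknown"
    area_m2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("known", "unknown_large", "unknown"):
            raise ValueError(f"bad patch-area kind {self.kind!r}")
        if self.kind == "known":
            if self.area_m2 is None or self.area_m2 < 0:
                raise ValueError("known patch area requires a non-negative area_m2")
        elif self.area_m2 is not None:
            raise ValueError(f"area_m2 given for kind {self.kind!r}")

    @classmethod
    def from_sentinel(cls, value: Optional[float]) -> "PatchArea":
        """Decode the I/O representation: blank -> unknown, -1 ->
        unknown-but-large, otherwise a known area in m^2."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return cls("unknown")
        if value == -1:
            return cls("unknown_large")
        return cls("known", float(value))

    def to_sentinel(self) -> Optional[float]:
        if self.kind == "known":
            return self.area_m2
        return -1.0 if self.kind == "unknown_large" else None


@dataclass
class SourceRecord:
    source_id: str
    bibliographic_citation: str
    declared_countries: List[str]
    provenance_kind: str = "journal article"

    def __post_init__(self) -> None:
        if not self.declared_countries:
            raise ValueError(f"source {self.source_id}: declared_countries empty")
        if self.provenance_kind not in PROVENANCE_KINDS:
            raise ValueError(f"source {self.source_id}: bad provenance {self.provenance_kind!r}")

    @property
    def multiple_countries(self) -> bool:
        return MULTIPLE_COUNTRIES in self.declared_countries


@dataclass
class StudyRecord:
    study_id: str
    source_id: str
    sampling_method: str
    effort_unit: str
    metric_type: str
    expected_clade: Optional[Tuple[str, str]] = None  # (rank, name), e.g. ("class", "Aves")
    lowest_common_taxon: Optional[Tuple[str, str]] = None  # computed after resolution

    def __post_init__(self) -> None:
        if self.metric_type not in METRIC_TYPES:
            raise ValueError(f"study {self.study_id}: bad metric type {self.metric_type!r}")


@dataclass
class SiteRecord:
    """A sampled location within a study.

    ``raw_start``/``raw_end`` keep the as-entered (year, month, day)
    parts so the validator can report impossible calendar dates;
    ``sampling_interval`` is None when the raw parts do not form a valid
    interval.  Coordinates may likewise be out of range here — range
    checking is the validation engine's job, since files are validated
    before their data are accepted.
    """

    site_id: str
    study_id: str
    latitude: Optional[float]
    longitude: Optional[float]
    habitat_description: str = ""
    land_use: Optional[LandUse] = None
    use_intensity: Optional[UseIntensity] = None
    fragmentation_layout: Optional[int] = None
    patch_area: PatchArea = field(default_factory=PatchArea)
    max_linear_extent: Optional[float] = None
    sampling_interval: Optional[DateInterval] = None
    raw_start: Optional[Tuple[int, Optional[int], Optional[int]]] = None
    raw_end: Optional[Tuple[int, Optional[int], Optional[int]]] = None
    effort: Optional[float] = None
    time_since_conversion: Optional[float] = None
    block: Optional[str] = None

    @property
    def key(self) -> Tuple[str, str]:
        return (self.study_id, self.site_id)


@dataclass
class DiversityMeasurement:
    study_id: str
    site_id: str
    taxon_id: str
    value: Optional[float]  # None = taxon not looked for at this site
    metric_type: str

    def __post_init__(self) -> None:
        if self.value is not None:
            if self.value < 0:
                raise ValueError(
                    f"measurement {self.study_id}/{self.site_id}/{self.taxon_id}: negative value"
                )
            if self.metric_type == "occurrence" and self.value not in (0.0, 1.0):
                raise ValueError(
                    f"measurement {self.study_id}/{self.site_id}/{self.taxon_id}: "
                    f"occurrence value {self.value} not in {{0, 1}}"
                )


@dataclass
class StudyBundle:
    """One incoming deposit: source metadata, its studies, sites, taxon
    names and per-study site-by-taxon matrices (rows = site ids, columns
    = taxon ids, NaN = blank cell)."""

    source: SourceRecord
    studies: List[StudyRecord]
    sites: List[SiteRecord]
    taxa: List["TaxonName"]  # forward ref; resolved at import bottom
    matrices: Dict[str, pd.DataFrame]  # study_id -> matrix


@dataclass
class SurveyDatabase:
    """The assembled, referentially checked collation.

    Sites and taxa are lists (not id-keyed maps) so that duplicated
    names — a data-entry error the validation engine must be able to
    report — remain representable after assembly.
    """

    sources: List[SourceRecord] = field(default_factory=list)
    studies: List[StudyRecord] = field(default_factory=list)
    sites: List[SiteRecord] = field(default_factory=list)
    taxa: List["TaxonName"] = field(default_factory=list)
    measurements: List[DiversityMeasurement] = field(default_factory=list)
    annotations: Dict[Tuple[str, str], "Annotation"] = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------
    def sites_of(self, study_id: str) -> List[SiteRecord]:
        return [s for s in self.sites if s.study_id == study_id]

    def taxa_of(self, study_id: str) -> List["TaxonName"]:
        return [t for t in self.taxa if t.study_id == study_id]

    def study(self, study_id: str) -> StudyRecord:
        for st in self.studies:
            if st.study_id == study_id:
                return st
        raise KeyError(study_id)

    def source(self, source_id: str) -> SourceRecord:
        for s in self.sources:
            if s.source_id == source_id:
                return s
        raise KeyError(source_id)

    def measurement_counts(self) -> Dict[Tuple[str, str], int]:
        """Non-missing measurements per site."""
        counts: Dict[Tuple[str, str], int] = {s.key: 0 for s in self.sites}
        for m in self.measurements:
            if m.value is not None:
                counts[(m.study_id, m.site_id)] += 1
        return counts

    @property
    def annotated(self) -> bool:
        return bool(self.annotations) and all(s.key in self.annotations for s in self.sites)


def interpret_matrix_blanks(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply the blank-cell interpretation rule to a site-by-taxon matrix.

    If every filled-in value is non-zero, blanks are zeros (taxa absent).
    If any filled-in value is zero, authors evidently recorded absences
    explicitly, so blanks mean the taxon was not looked for at that site
    and become missing values.  Filled cells are never changed; the rule
    is applied per incoming study matrix.

    Raises ``AssemblyError`` on negative cells.
    """
    values = matrix.to_numpy(dtype=float, na_value=float("nan"))
    filled = values[~pd.isna(values)]
    if (filled < 0).any():
        bad = matrix.stack()
        loc = bad[bad < 0].index[0]
        raise AssemblyError(f"negative matrix cell at site {loc[0]!r}, taxon {loc[1]!r}")
    out = matrix.astype(float).copy()
    if len(filled) and (filled != 0).all():
        out = out.fillna(0.0)
    return out


def assemble_database(bundles: Sequence[StudyBundle]) -> SurveyDatabase:
    """Assemble validated study bundles into a :class:`SurveyDatabase`.

    Enforces structural invariants: unique source/study ids, resolvable
    foreign references, at least two sites per study, one matrix per
    study whose rows/columns reference that study's sites/taxa.  Blank
    matrix cells are interpreted per :func:`interpret_matrix_blanks`.
    Field-level data problems (bad coordinates, impossible dates,
    duplicate names...) are left for the validation engine to report.
    """
    db = SurveyDatabase()
    seen_sources: set = set()
    seen_studies: set = set()
    for bundle in bundles:
        src = bundle.source
        if src.source_id in seen_sources:
            raise AssemblyError(f"duplicate source id {src.source_id!r}")
        seen_sources.add(src.source_id)
        db.sources.append(src)
        if not bundle.studies:
            raise AssemblyError(f"source {src.source_id!r} has no studies")
        for study in bundle.studies:
            if study.source_id != src.source_id:
                raise AssemblyError(
                    f"study {study.study_id!r} references source {study.source_id!r}, "
                    f"not bundle source {src.source_id!r}"
                )
            if study.study_id in seen_studies:
                raise AssemblyError(f"duplicate study id {study.study_id!r}")
            seen_studies.add(study.study_id)
            db.studies.append(study)

            sites = [s for s in bundle.sites if s.study_id == study.study_id]
            if len(sites) < 2:
                raise AssemblyError(
                    f"study {study.study_id!r} has {len(sites)} site(s); a study "
                    f"contains two or more sites"
                )
            db.sites.extend(sites)
            taxa = [t for t in bundle.taxa if t.study_id == study.study_id]
            db.taxa.extend(taxa)

            if study.study_id not in bundle.matrices:
                raise AssemblyError(f"study {study.study_id!r} has no matrix")
            matrix = interpret_matrix_blanks(bundle.matrices[study.study_id])

            site_ids = {s.site_id for s in sites}
            taxon_ids = {t.taxon_id for t in taxa}
            for sid in matrix.index:
                if sid not in site_ids:
                    raise AssemblyError(
                        f"matrix of study {study.study_id!r} references unknown site {sid!r}"
                    )
            for tid in matrix.columns:
                if tid not in taxon_ids:
                    raise AssemblyError(
                        f"matrix of study {study.study_id!r} references unknown taxon {tid!r}"
                    )
            values = matrix.to_numpy(dtype=float, na_value=float("nan"))
            for i, sid in enumerate(matrix.index):  # positional: ids may be duplicated
                for j, tid in enumerate(matrix.columns):
                    v = values[i, j]
                    db.measurements.append(
                        DiversityMeasurement(
                            study_id=study.study_id,
                            site_id=sid,
                            taxon_id=tid,
                            value=None if pd.isna(v) else float(v),
                            metric_type=study.metric_type,
                        )
                    )
    return db


#: Fixed column order of the site extract.
SITE_EXTRACT_COLUMNS = [
    "source_id",
    "study_id",
    "site_id",
    "land_use",
    "use_intensity",
    "fragmentation_layout",
    "longitude",
    "latitude",
    "sample_start_earliest",
    "sample_end_latest",
    "sample_date_resolution",
    "country",
    "realm",
    "biome",
    "ecoregion",
    "hotspot",
    "taxonomic_group",
    "n_measurements",
]


def site_extract(db: SurveyDatabase) -> pd.DataFrame:
    """One summary row per site: land use, use intensity, fragmentation,
    coordinates, sampling dates, country, realm, biome, ecoregion,
    hotspot, taxonomic group studied and the number of (non-missing)
    measurements.

    Requires the database to have been geographically annotated and its
    taxa resolved; raises ``ValueError`` instructing to run those steps
    otherwise.
    """
    from .taxonomy import study_taxonomic_group  # local import avoids cycle

    if not db.annotated:
        raise ValueError("database not annotated: run annotate_sites() first")
    if any(t.resolution is None for t in db.taxa):
        raise ValueError("taxa not resolved: run resolve_database() first")

    counts = db.measurement_counts()
    groups = {st.study_id: study_taxonomic_group(db, st.study_id) for st in db.studies}
    rows = []
    for site in db.sites:
        study = db.study(site.study_id)
        ann = db.annotations[site.key]
        interval = site.sampling_interval
        rows.append(
            {
                "source_id": study.source_id,
                "study_id": site.study_id,
                "site_id": site.site_id,
                "land_use": site.land_use.label() if site.land_use else "",
                "use_intensity": site.use_intensity.value if site.use_intensity else "",
                "fragmentation_layout": site.fragmentation_layout if site.fragmentation_layout else "",
                "longitude": site.longitude,
                "latitude": site.latitude,
                "sample_start_earliest": interval.earliest_start.isoformat() if interval else "",
                "sample_end_latest": interval.latest_end.isoformat() if interval else "",
                "sample_date_resolution": interval.resolution if interval else "",
                "country": ann.attributes.get("country", ""),
                "realm": ann.attributes.get("realm", ""),
                "biome": ann.attributes.get("biome", ""),
                "ecoregion": ann.attributes.get("ecoregion", ""),
                "hotspot": ann.attributes.get("hotspot", ""),
                "taxonomic_group": groups[site.study_id],
                "n_measurements": counts[site.key],
            }
        )
    return pd.DataFrame(rows, columns=SITE_EXTRACT_COLUMNS)


# late imports for dataclass forward references
from .taxonomy import TaxonName  # noqa: E402
from .geo import Annotation  # noqa: E402
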