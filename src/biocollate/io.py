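"""Readers and writers for the package's file dialects, plus the
pipeline configuration and the end-to-end pipeline.

Dialects: UTF-8 CSV (BOM tolerated), comma-separated, header row
mandatory, dates ISO-8601 with the date resolution in its own column.
A study bundle is a directory of source.csv, studies.csv, sites.csv,
taxa.csv and matrix.csv (sites as rows, first column the site id).
Region layers are GeoJSON in WGS84; the NPP raster is one ESRI-ASCII
grid per month plus a terrestrial-fraction mask.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import shape

from .geo import NPPRaster, RegionLayer, annotate_sites
from .model import (
    PatchArea,
    SiteRecord,
    SourceRecord,
    StudyBundle,
    StudyRecord,
    SurveyDatabase,
    assemble_database,
    site_extract,
)
from .siteattrs import DateInterval, LandUse, UseIntensity, make_date_interval
from .taxonomy import (
    Checklist,
    ChecklistEntry,
    CladeConstraint,
    RANKS,
    TaxonName,
    apply_curation,
    build_review_queue,
    resolve_database,
)

log = logging.getLogger("biocollate")


class ParseError(ValueError):
    """A file violated its dialect; the message names the file and line."""


def _read_rows(path: Path) -> List[Dict[str, str]]:
    """Read a CSV into dict rows, enforcing a rectangular table and
    reporting the offending line number otherwise."""
    with open(path, encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (header row is mandatory)")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {len(header)}"
                )
            rows.append(dict(zip(header, row)))
    return rows


def _opt_float(text: str) -> Optional[float]:
    text = text.strip()
    return float(text) if text else None


def _opt_int(text: str) -> Optional[int]:
    text = text.strip()
    return int(text) if text else None


# ---------------------------------------------------------------------------
# Study bundles


def write_bundle(bundle: StudyBundle, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    s = bundle.source
    pd.DataFrame(
        [
            {
                "source_id": s.source_id,
                "bibliographic_citation": s.bibliographic_citation,
                "declared_countries": ";".join(s.declared_countries),
                "provenance_kind": s.provenance_kind,
            }
        ]
    ).to_csv(directory / "source.csv", index=False)
    pd.DataFrame(
        [
            {
                "study_id": st.study_id,
                "source_id": st.source_id,
                "sampling_method": st.sampling_method,
                "effort_unit": st.effort_unit,
                "metric_type": st.metric_type,
                "expected_clade_rank": st.expected_clade[0] if st.expected_clade else "",
                "expected_clade_name": st.expected_clade[1] if st.expected_clade else "",
            }
            for st in bundle.studies
        ]
    ).to_csv(directory / "studies.csv", index=False)

    site_rows = []
    for site in bundle.sites:
        rs, re_ = site.raw_start, site.raw_end
        site_rows.append(
            {
                "site_id": site.site_id,
                "study_id": site.study_id,
                "latitude": "" if site.latitude is None else site.latitude,
                "longitude": "" if site.longitude is None else site.longitude,
                "habitat_description": site.habitat_description,
                "land_use": site.land_use.label() if site.land_use else "",
                "use_intensity": site.use_intensity.value if site.use_intensity else "",
                "fragmentation_layout": site.fragmentation_layout or "",
                "patch_area": (
                    "" if site.patch_area.to_sentinel() is None else site.patch_area.to_sentinel()
                ),
                "max_linear_extent": site.max_linear_extent or "",
                "start_year": rs[0] if rs else "",
                "start_month": (rs[1] if rs and rs[1] is not None else "") if rs else "",
                "start_day": (rs[2] if rs and rs[2] is not None else "") if rs else "",
                "end_year": re_[0] if re_ else "",
                "end_month": (re_[1] if re_ and re_[1] is not None else "") if re_ else "",
                "end_day": (re_[2] if re_ and re_[2] is not None else "") if re_ else "",
                "effort": "" if site.effort is None else site.effort,
                "time_since_conversion": (
                    "" if site.time_since_conversion is None else site.time_since_conversion
                ),
                "block": site.block or "",
            }
        )
    pd.DataFrame(site_rows).to_csv(directory / "sites.csv", index=False)

    pd.DataFrame(
        [
            {"taxon_id": t.taxon_id, "study_id": t.study_id, "name_entered": t.name_entered}
            for t in bundle.taxa
        ]
    ).to_csv(directory / "taxa.csv", index=False)

    frames = []
    for study_id, m in bundle.matrices.items():
        f = m.copy()
        f.insert(0, "site_id", f.index)
        f.insert(0, "study_id", study_id)
        frames.append(f)
    big = pd.concat(frames, axis=0, ignore_index=True)
    big.to_csv(directory / "matrix.csv", index=False)


def read_bundle(directory: Path) -> StudyBundle:
    directory = Path(directory)
    src_rows = _read_rows(directory / "source.csv")
    if len(src_rows) != 1:
        raise ParseError(f"{directory / 'source.csv'}: expected exactly one source row")
    r = src_rows[0]
    source = SourceRecord(
        source_id=r["source_id"],
        bibliographic_citation=r["bibliographic_citation"],
        declared_countries=[c for c in r["declared_countries"].split(";") if c],
        provenance_kind=r["provenance_kind"],
    )
    studies = []
    for r in _read_rows(directory / "studies.csv"):
        clade = None
        if r.get("expected_clade_rank") and r.get("expected_clade_name"):
            clade = (r["expected_clade_rank"], r["expected_clade_name"])
        studies.append(
            StudyRecord(
                study_id=r["study_id"],
                source_id=r["source_id"],
                sampling_method=r["sampling_method"],
                effort_unit=r["effort_unit"],
                metric_type=r["metric_type"],
                expected_clade=clade,
            )
        )
    sites = []
    for r in _read_rows(directory / "sites.csv"):
        raw_start = raw_end = None
        interval = None
        if r["start_year"].strip():
            raw_start = (int(r["start_year"]), _opt_int(r["start_month"]), _opt_int(r["start_day"]))
            raw_end = (int(r["end_year"]), _opt_int(r["end_month"]), _opt_int(r["end_day"]))
            try:
                interval = make_date_interval(*raw_start, *raw_end)
            except ValueError:
                interval = None  # the validator reports it
        sites.append(
            SiteRecord(
                site_id=r["site_id"],
                study_id=r["study_id"],
                latitude=_opt_float(r["latitude"]),
                longitude=_opt_float(r["longitude"]),
                habitat_description=r.get("habitat_description", ""),
                land_use=LandUse.from_label(r["land_use"]) if r["land_use"].strip() else None,
                use_intensity=(
                    UseIntensity(r["use_intensity"]) if r["use_intensity"].strip() else None
                ),
                fragmentation_layout=_opt_int(r["fragmentation_layout"]),
                patch_area=PatchArea.from_sentinel(_opt_float(r["patch_area"])),
                max_linear_extent=_opt_float(r["max_linear_extent"]),
                sampling_interval=interval,
                raw_start=raw_start,
                raw_end=raw_end,
                effort=_opt_float(r["effort"]),
                time_since_conversion=_opt_float(r["time_since_conversion"]),
                block=r.get("block", "") or None,
            )
        )
    taxa = [
        TaxonName(taxon_id=r["taxon_id"], study_id=r["study_id"], name_entered=r["name_entered"])
        for r in _read_rows(directory / "taxa.csv")
    ]
    matrices: Dict[str, pd.DataFrame] = {}
    big = pd.read_csv(directory / "matrix.csv", encoding="utf-8-sig", dtype={"site_id": str})
    taxa_by_study: Dict[str, List[str]] = {}
    for t in taxa:
        taxa_by_study.setdefault(t.study_id, []).append(t.taxon_id)
    for study_id, group in big.groupby("study_id", sort=False):
        cols = [c for c in taxa_by_study.get(study_id, []) if c in group.columns]
        m = group.set_index("site_id")[cols]
        matrices[str(study_id)] = m
    return StudyBundle(source, studies, sites, taxa, matrices)


# ---------------------------------------------------------------------------
# Checklist

_CHECKLIST_COLUMNS = ["entry_id", "name", "rank", "status", "accepted_ref", *RANKS, "common_names"]


def write_checklist(checklist: Checklist, path: Path) -> None:
    rows = []
    for e in checklist.entries.values():
        row = {
            "entry_id": e.entry_id,
            "name": e.name,
            "rank": e.rank,
            "status": e.status,
            "accepted_ref": e.accepted_ref,
            "common_names": ";".join(e.common_names),
        }
        for rank in RANKS:
            row[rank] = e.classification.get(rank, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_CHECKLIST_COLUMNS).to_csv(path, index=False)


def read_checklist(path: Path) -> Checklist:
    entries = []
    for r in _read_rows(Path(path)):
        classification = {rank: r[rank] for rank in RANKS if r.get(rank, "").strip()}
        entries.append(
            ChecklistEntry(
                entry_id=r["entry_id"],
                name=r["name"],
                rank=r["rank"],
                status=r["status"],
                accepted_ref=r["accepted_ref"],
                classification=classification,
                common_names=tuple(c for c in r.get("common_names", "").split(";") if c),
            )
        )
    return Checklist(entries)


# ---------------------------------------------------------------------------
# Region layers (GeoJSON) and NPP rasters (ESRI ASCII)


def write_layer(layer: RegionLayer, path: Path) -> None:
    from shapely.geometry import mapping

    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": attrs}
        for geom, attrs in layer.features
    ]
    payload = {"type": "FeatureCollection", "name": layer.layer_name, "features": features}
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_layer(path: Path, layer_name: Optional[str] = None) -> RegionLayer:
    payload = json.loads(Path(path).read_text(encoding="utf-8-sig"))
    if payload.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: expected a GeoJSON FeatureCollection")
    features = []
    for i, feat in enumerate(payload.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ParseError(f"{path}: feature {i}: bad geometry ({exc})")
        props = {k: str(v) for k, v in (feat.get("properties") or {}).items()}
        features.append((geom, props))
    return RegionLayer(layer_name or payload.get("name", Path(path).stem), features)


def write_raster(raster: NPPRaster, directory: Path, prefix: str = "npp") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def _write_grid(grid: np.ndarray, path: Path) -> None:
        nrows, ncols = grid.shape
        lines = [
            f"ncols {ncols}",
            f"nrows {nrows}",
            f"xllcorner {raster.xllcorner}",
            f"yllcorner {raster.yllcorner}",
            f"cellsize {raster.cellsize}",
            "NODATA_value -9999",
        ]
        for r in range(nrows):
            vals = ["-9999" if math.isnan(v) else f"{v:.6g}" for v in grid[r]]
            lines.append(" ".join(vals))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    for m in range(12):
        _write_grid(raster.months[m], directory / f"{prefix}_{m + 1:02d}.asc")
    _write_grid(raster.mask, directory / f"{prefix}_mask.asc")


def _read_grid(path: Path) -> Tuple[np.ndarray, Dict[str, float]]:
    header: Dict[str, float] = {}
    rows: List[List[float]] = []
    nodata = -9999.0
    with open(path, encoding="utf-8-sig") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                                    "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
                if parts[0].lower() == "nodata_value":
                    nodata = float(parts[1])
            else:
                try:
                    rows.append([float(p) for p in parts])
                except ValueError:
                    raise ParseError(f"{path}: line {lineno}: non-numeric grid value")
    grid = np.array(rows, dtype=float)
    if grid.shape != (int(header.get("nrows", -1)), int(header.get("ncols", -1))):
        raise ParseError(f"{path}: grid shape {grid.shape} does not match header")
    grid[grid == nodata] = np.nan
    return grid, header


def read_raster(directory: Path, prefix: str = "npp") -> NPPRaster:
    directory = Path(directory)
    grids = []
    header = None
    for m in range(12):
        grid, h = _read_grid(directory / f"{prefix}_{m + 1:02d}.asc")
        grids.append(grid)
        header = h
    mask_path = directory / f"{prefix}_mask.asc"
    if mask_path.exists():
        mask, _ = _read_grid(mask_path)
        mask = np.nan_to_num(mask, nan=0.0)
    else:
        mask = np.ones_like(grids[0])  # default: fully terrestrial
    return NPPRaster(
        months=np.stack(grids),
        mask=mask,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
    )


# ---------------------------------------------------------------------------
# Issues / reports


def write_issues(issues: Sequence, path: Path) -> None:
    pd.DataFrame(
        [
            {"code": i.code, "severity": i.severity, "record_ref": i.record_ref,
             "message": i.message}
            for i in issues
        ],
        columns=["code", "severity", "record_ref", "message"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration and runner


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, JSON round-trippable."""

    bundle_dirs: List[str]
    checklist_path: str
    ecoregions_path: str
    countries_path: str
    hotspots_path: Optional[str] = None
    raster_dir: Optional[str] = None
    output_dir: str = "out"
    offshore_threshold_m: float = 10_000.0
    near_miss_weight: float = 0.5
    #: study_id -> (rank, name) clade constraints for name resolution
    clade_constraints: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    #: curation overrides: (study_id, taxon_id) -> (new query, reason)
    seed: int = 0
    strict: bool = False

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["clade_constraints"] = {
            k: tuple(v) for k, v in (d.get("clade_constraints") or {}).items()
        }
        return cls(**d)


@dataclass
class PipelineResult:
    database: SurveyDatabase
    issues: List
    review_queue: List
    extract: Optional[pd.DataFrame]
    summary: Dict[str, object]
    ok: bool


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Assemble, validate (abort on errors), resolve taxonomy, build the
    review queue, annotate, and write the site extract and reports.

    Stage order mirrors the collation workflow: files are fully
    validated before their data enter the database.
    """
    from . import validation as V

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {"seed": config.seed}

    bundles = [read_bundle(Path(d)) for d in config.bundle_dirs]
    db = assemble_database(bundles)
    summary["sources"] = len(db.sources)
    summary["studies"] = len(db.studies)
    summary["sites"] = len(db.sites)
    summary["taxa"] = len(db.taxa)
    summary["measurements"] = sum(1 for m in db.measurements if m.value is not None)
    log.info("assembled %s sources, %s studies, %s sites", len(db.sources), len(db.studies),
             len(db.sites))

    countries = read_layer(Path(config.countries_path), "countries")
    issues = V.validate_with_gis(db, countries)
    write_issues(issues, out / "validation_issues.csv")
    summary["validation_issues"] = len(issues)
    blocking = [i for i in issues if i.severity == "error"
                or (config.strict and i.severity == "warning")]
    if blocking:
        log.error("validation failed with %d blocking issue(s)", len(blocking))
        summary["ok"] = False
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        return PipelineResult(db, issues, [], None, summary, ok=False)

    checklist = read_checklist(Path(config.checklist_path))
    constraints = {
        k: CladeConstraint(rank, name) for k, (rank, name) in config.clade_constraints.items()
    }
    resolve_database(db, checklist, constraints)
    queue = build_review_queue(db, checklist)
    write_issues(
        [V.ValidationIssue(f.criterion, "review", f.record_ref, f.detail) for f in queue],
        out / "review_queue.csv",
    )
    summary["review_queue"] = len(queue)

    ecoregions = read_layer(Path(config.ecoregions_path), "ecoregions")
    hotspots = read_layer(Path(config.hotspots_path), "hotspots") if config.hotspots_path else None
    annotate_sites(db, ecoregions, countries, hotspots)
    offshore = V.flag_offshore_sites(db, config.offshore_threshold_m)
    write_issues(offshore, out / "offshore_review.csv")
    summary["offshore_flags"] = len(offshore)

    extract = site_extract(db)
    extract.to_csv(out / "site_extract.csv", index=False)
    summary["extract_rows"] = len(extract)

    from .geo import coverage_table, latitudinal_coverage

    for attr in ("biome", "hotspot", "country"):
        coverage_table(db, attr).to_csv(out / f"coverage_{attr}.csv", index=False)
    latitudinal_coverage(db).to_csv(out / "coverage_latitude.csv", index=False)

    from .taxonomy import aggregate_group_counts, count_species

    counts, total = count_species(db)
    summary["species_estimate"] = total
    pd.Series(aggregate_group_counts(counts), name="species").rename_axis("group").to_csv(
        out / "species_counts.csv"
    )

    summary["ok"] = True
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return PipelineResult(db, issues, queue, extract, summary, ok=True)
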