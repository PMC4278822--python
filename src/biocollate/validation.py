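"""Data-validation engine.

Incoming files are fully validated before their data are accepted into a
collation.  Lower-level rules catch missing mandatory fields, negative
times since conversion, out-of-range coordinates and angle literals
(a latitude of 1° 61'), impossible calendar dates (32nd January) and
duplicated site or taxon names within a study.  Higher-level rules catch
coordinate mistakes — swapped latitude/longitude, mis-assembled DMS
components, swapped hemisphere signs — which typically plot sites in the
wrong country or out to sea; they are detected by requiring that the
GIS-matched country agrees with the country declared in the metadata,
and by reviewing sites at a non-zero distance from any country polygon.

Issues are values, not exceptions: validation returns the full list so a
depositor can fix everything in one round.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, TYPE_CHECKING

from .geo import RegionLayer, match_nearest
from .model import SurveyDatabase

if TYPE_CHECKING:  # pragma: no cover
    from .model import SiteRecord

# Rule codes
MISSING_MANDATORY = "MISSING_MANDATORY"
NEGATIVE_CONVERSION_TIME = "NEGATIVE_CONVERSION_TIME"
COORD_OUT_OF_RANGE = "COORD_OUT_OF_RANGE"
BAD_ANGLE = "BAD_ANGLE"
INVALID_DATE = "INVALID_DATE"
DUPLICATE_SITE_NAME = "DUPLICATE_SITE_NAME"
DUPLICATE_TAXON_NAME = "DUPLICATE_TAXON_NAME"
COUNTRY_MISMATCH = "COUNTRY_MISMATCH"
OFFSHORE_SITE = "OFFSHORE_SITE"

#: Severity of each rule.  The checks themselves are unranked in origin;
#: this fixed mapping is configuration, not science.
SEVERITY: Dict[str, str] = {
    MISSING_MANDATORY: "error",
    NEGATIVE_CONVERSION_TIME: "error",
    COORD_OUT_OF_RANGE: "error",
    BAD_ANGLE: "error",
    INVALID_DATE: "error",
    DUPLICATE_SITE_NAME: "error",
    DUPLICATE_TAXON_NAME: "error",
    COUNTRY_MISMATCH: "error",
    OFFSHORE_SITE: "review",
}


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    severity: str
    record_ref: str
    message: str


def _issue(code: str, ref: str, message: str, severity: Optional[str] = None) -> ValidationIssue:
    return ValidationIssue(code, severity or SEVERITY[code], ref, message)


# ---------------------------------------------------------------------------
# Angle literals

_ANGLE_RE = re.compile(
    r"""^\s*
    (?P<deg>[+-]?\d+(?:\.\d+)?)\s*(?:°|º|d\b|deg\b)?
    (?:\s*(?P<min>\d+(?:\.\d+)?)\s*['′m]?)?
    (?:\s*(?P<sec>\d+(?:\.\d+)?)\s*["″s]?)?
    \s*(?P<hemi>[NSEWnsew])?\s*$""",
    re.VERBOSE,
)


class AngleError(ValueError):
    """An angle literal with out-of-range minutes or seconds."""


def parse_angle(text: str) -> float:
    """Parse a coordinate literal into decimal degrees.

    Accepts plain decimals ("12.25", "-1.5") and degrees-minutes-seconds
    forms with an optional hemisphere letter ("1° 30' S" -> -1.5).
    Minutes and seconds must be < 60: "1° 61'" is the canonical invalid
    literal and raises :class:`AngleError`.
    """
    if not text or not text.strip():
        raise ValueError("empty coordinate")
    m = _ANGLE_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable coordinate {text!r}")
    deg = float(m.group("deg"))
    minutes = float(m.group("min")) if m.group("min") else 0.0
    seconds = float(m.group("sec")) if m.group("sec") else 0.0
    has_dms = m.group("min") is not None or m.group("sec") is not None
    if not 0 <= minutes < 60:
        raise AngleError(f"minutes {minutes:g} out of range in {text!r}")
    if not 0 <= seconds < 60:
        raise AngleError(f"seconds {seconds:g} out of range in {text!r}")
    if has_dms and deg < 0:
        raise ValueError(f"signed degrees with DMS components in {text!r}")
    value = abs(deg) + minutes / 60.0 + seconds / 3600.0
    if deg < 0:
        value = -value
    hemi = (m.group("hemi") or "").upper()
    if hemi in ("S", "W"):
        if deg < 0:
            raise ValueError(f"both sign and hemisphere in {text!r}")
        value = -value
    return value


# ---------------------------------------------------------------------------
# Database-level rules


def _valid_date_parts(parts: Optional[Tuple[int, Optional[int], Optional[int]]]) -> bool:
    if parts is None:
        return False
    year, month, day = parts
    if month is None:
        return day is None
    if not 1 <= month <= 12:
        return False
    if day is None:
        return True
    return 1 <= day <= calendar.monthrange(year, month)[1]


def validate_database(db: SurveyDatabase) -> List[ValidationIssue]:
    """Run the lower-level rule set over an assembled database.

    Rules: mandatory-field presence (ids, coordinates, sampling dates,
    metric type, effort unit), non-negative time since conversion,
    coordinate ranges, calendar-date validity on the as-entered date
    parts, and duplicate site/taxon names within a study.  An empty list
    means every implemented rule passes.
    """
    issues: List[ValidationIssue] = []
    for site in db.sites:
        ref = f"study {site.study_id}/site {site.site_id}"
        if site.latitude is None or site.longitude is None:
            issues.append(_issue(MISSING_MANDATORY, ref, "coordinates are mandatory"))
        else:
            if not -90.0 <= site.latitude <= 90.0:
                issues.append(
                    _issue(COORD_OUT_OF_RANGE, ref, f"latitude {site.latitude} outside [-90, 90]")
                )
            if not -180.0 <= site.longitude <= 180.0:
                issues.append(
                    _issue(
                        COORD_OUT_OF_RANGE, ref, f"longitude {site.longitude} outside [-180, 180]"
                    )
                )
        if site.raw_start is None and site.raw_end is None and site.sampling_interval is None:
            issues.append(_issue(MISSING_MANDATORY, ref, "sampling dates are mandatory"))
        else:
            for label, parts in (("start", site.raw_start), ("end", site.raw_end)):
                if parts is not None and not _valid_date_parts(parts):
                    issues.append(
                        _issue(INVALID_DATE, ref, f"{label} date {parts} is not a calendar date")
                    )
        if site.time_since_conversion is not None and site.time_since_conversion < 0:
            issues.append(
                _issue(
                    NEGATIVE_CONVERSION_TIME,
                    ref,
                    f"time since conversion {site.time_since_conversion} is negative",
                )
            )
        if site.max_linear_extent is not None and site.max_linear_extent <= 0:
            issues.append(
                _issue(MISSING_MANDATORY, ref, "max linear extent must be positive when given")
            )

    for study in db.studies:
        ref = f"study {study.study_id}"
        if not study.effort_unit:
            issues.append(_issue(MISSING_MANDATORY, ref, "effort unit is mandatory"))
        seen_sites: Dict[str, int] = {}
        for site in db.sites_of(study.study_id):
            seen_sites[site.site_id] = seen_sites.get(site.site_id, 0) + 1
        for name, n in seen_sites.items():
            if n > 1:
                issues.append(
                    _issue(
                        DUPLICATE_SITE_NAME,
                        f"{ref}/site {name}",
                        f"site name {name!r} appears {n} times in {study.study_id}",
                    )
                )
        seen_taxa: Dict[str, int] = {}
        for taxon in db.taxa_of(study.study_id):
            key = taxon.name_entered.strip()
            seen_taxa[key] = seen_taxa.get(key, 0) + 1
        for name, n in seen_taxa.items():
            if n > 1:
                issues.append(
                    _issue(
                        DUPLICATE_TAXON_NAME,
                        f"{ref}/taxon {name}",
                        f"taxon name {name!r} appears {n} times in {study.study_id}",
                    )
                )
    return issues


def check_country_consistency(
    site: "SiteRecord",
    declared_countries: Sequence[str],
    countries: RegionLayer,
) -> Optional[ValidationIssue]:
    """Require the GIS-matched (nearest) country to be among the declared
    countries.  A declaration of "Multiple countries" always passes.
    Returns None on a pass, a COUNTRY_MISMATCH issue otherwise."""
    from .model import MULTIPLE_COUNTRIES

    if MULTIPLE_COUNTRIES in declared_countries:
        return None
    attrs, _d = match_nearest(countries, site.latitude, site.longitude)
    matched = attrs.get("country", "")
    if matched in declared_countries:
        return None
    return _issue(
        COUNTRY_MISMATCH,
        f"study {site.study_id}/site {site.site_id}",
        f"coordinates plot in {matched!r} but metadata declares {list(declared_countries)}",
    )


#: Candidate repairs for coordinates that plot in the wrong country, in
#: the order the underlying mistakes are typically made.
_TRANSFORMS = (
    ("swap_lat_lon", lambda lat, lon: (lon, lat)),
    ("negate_lat", lambda lat, lon: (-lat, lon)),
    ("negate_lon", lambda lat, lon: (lat, -lon)),
    ("negate_both", lambda lat, lon: (-lat, -lon)),
)


def suggest_coordinate_fixes(
    site: "SiteRecord",
    declared_countries: Sequence[str],
    countries: RegionLayer,
) -> List[Tuple[str, Tuple[float, float], float]]:
    """For a site that failed the country-consistency check, evaluate the
    standard coordinate repairs (swap latitude/longitude; negate either
    or both, i.e. hemisphere swaps) and return those whose result lands
    in — or nearest to — a declared country, as
    (transform name, (lat, lon), distance m) sorted by distance.  Never
    mutates anything; suggestions are for human review."""
    out = []
    for name, f in _TRANSFORMS:
        lat, lon = f(site.latitude, site.longitude)
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            continue
        attrs, d = match_nearest(countries, lat, lon)
        if attrs.get("country", "") in declared_countries:
            out.append((name, (lat, lon), d))
    out.sort(key=lambda t: t[2])
    return out


def flag_offshore_sites(
    db: SurveyDatabase, threshold_m: float = 10_000.0
) -> List[ValidationIssue]:
    """Flag annotated sites at a non-zero distance from every country
    polygon (coasts, small islands, or genuinely wrong coordinates) for
    review; distances beyond ``threshold_m`` escalate to warnings.
    Requires prior annotation (the distances live there)."""
    if not db.annotated:
        raise ValueError("database not annotated: run annotate_sites() first")
    issues = []
    for site in db.sites:
        d = db.annotations[site.key].distances.get("country", 0.0)
        if d > 0:
            severity = "warning" if d > threshold_m else "review"
            issues.append(
                _issue(
                    OFFSHORE_SITE,
                    f"study {site.study_id}/site {site.site_id}",
                    f"site is {d:.0f} m from the nearest country polygon",
                    severity=severity,
                )
            )
    return issues


def validate_with_gis(
    db: SurveyDatabase, countries: RegionLayer
) -> List[ValidationIssue]:
    """Lower-level rules plus country-consistency for every site whose
    coordinates are present and in range."""
    issues = validate_database(db)
    flagged = {
        i.record_ref for i in issues if i.code in (COORD_OUT_OF_RANGE, MISSING_MANDATORY)
    }
    for site in db.sites:
        ref = f"study {site.study_id}/site {site.site_id}"
        if ref in flagged or site.latitude is None or site.longitude is None:
            continue
        study = db.study(site.study_id)
        declared = db.source(study.source_id).declared_countries
        issue = check_country_consistency(site, declared, countries)
        if issue is not None:
            issues.append(issue)
    return issues
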