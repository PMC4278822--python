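"""Site-attribute ontology: land use, use intensity, fragmentation,
sampling-date intervals, time-since-conversion parsing, near-miss
relations and maximum linear extent.

The land-use classification follows the five Representative Concentration
Pathways harmonised land-use classes (primary vegetation, secondary
vegetation, cropland, pasture, urban) extended with plantation forest and
a "Cannot decide" class for sites with insufficient information.
Secondary vegetation is subdivided by successional stage (young,
intermediate, mature, or indeterminate when stage is unknown).  Use
intensity is minimal, light or intense, again with "Cannot decide".

Assigning these classes from free-text habitat descriptions is a trained
human task and is deliberately out of scope here: this module supplies
the enumerations, validates entered combinations, and defines the
"near miss" relations used to give partial credit in repeatability
analyses.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import itertools
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

from .sphere import great_circle_m


class LandUseClass(str, Enum):
    PRIMARY = "Primary vegetation"
    SECONDARY = "Secondary vegetation"
    CROPLAND = "Cropland"
    PASTURE = "Pasture"
    URBAN = "Urban"
    PLANTATION = "Plantation forest"
    CANNOT_DECIDE = "Cannot decide"


class SecondaryStage(str, Enum):
    YOUNG = "Young"
    INTERMEDIATE = "Intermediate"
    MATURE = "Mature"
    INDETERMINATE = "Indeterminate"


class UseIntensity(str, Enum):
    MINIMAL = "Minimal use"
    LIGHT = "Light use"
    INTENSE = "Intense use"
    CANNOT_DECIDE = "Cannot decide"


#: Fragmentation layouts 1-5: (1) well within unfragmented habitat,
#: (2) within unfragmented habitat but at or near its edge, (3) within a
#: remnant patch surrounded by other habitats, (4) representative part of
#: a fragmented landscape, (5) part of the matrix surrounding remnant
#: patches.
FRAGMENTATION_LAYOUTS = (1, 2, 3, 4, 5)

_STAGE_ORDER = {
    SecondaryStage.YOUNG: 0,
    SecondaryStage.INTERMEDIATE: 1,
    SecondaryStage.MATURE: 2,
}

_INTENSITY_ORDER = {
    UseIntensity.MINIMAL: 0,
    UseIntensity.LIGHT: 1,
    UseIntensity.INTENSE: 2,
}


@dataclass(frozen=True)
class LandUse:
    """A predominant land-use assignment.

    ``stage`` must be present exactly when the class is secondary
    vegetation (use ``SecondaryStage.INDETERMINATE`` when the stage is
    unknown).
    """

    land_use: LandUseClass
    stage: Optional[SecondaryStage] = None

    def __post_init__(self) -> None:
        if self.land_use is LandUseClass.SECONDARY:
            if self.stage is None:
                raise ValueError("secondary vegetation requires a stage "
                                 "(use SecondaryStage.INDETERMINATE if unknown)")
        elif self.stage is not None:
            raise ValueError(f"stage given for non-secondary class {self.land_use.value!r}")

    def label(self) -> str:
        if self.land_use is LandUseClass.SECONDARY:
            return f"{self.land_use.value} ({self.stage.value})"
        return self.land_use.value

    @classmethod
    def from_label(cls, text: str) -> "LandUse":
        text = text.strip()
        m = re.fullmatch(r"Secondary vegetation \((\w+)\)", text)
        if m:
            return cls(LandUseClass.SECONDARY, SecondaryStage(m.group(1).capitalize()))
        if text == LandUseClass.SECONDARY.value:
            return cls(LandUseClass.SECONDARY, SecondaryStage.INDETERMINATE)
        return cls(LandUseClass(text))


@dataclass(frozen=True)
class DateInterval:
    """A sampling-date interval at a stated resolution.

    Authors report sampling dates at day, month or year precision.  The
    interval stores the earliest possible start day and the latest
    possible end day consistent with what was reported, plus the
    resolution, so that ordinary date columns can carry imprecise dates
    without losing the precision information.
    """

    earliest_start: _dt.date
    latest_end: _dt.date
    resolution: str  # "day" | "month" | "year"

    def __post_init__(self) -> None:
        if self.resolution not in ("day", "month", "year"):
            raise ValueError(f"bad resolution {self.resolution!r}")
        if self.earliest_start > self.latest_end:
            raise ValueError("interval start after end")
        s, e = self.earliest_start, self.latest_end
        if self.resolution == "month":
            if s.day != 1 or e.day != calendar.monthrange(e.year, e.month)[1]:
                raise ValueError("month-resolution interval not snapped to month bounds")
        elif self.resolution == "year":
            if (s.month, s.day) != (1, 1) or (e.month, e.day) != (12, 31):
                raise ValueError("year-resolution interval not snapped to year bounds")


def make_date_interval(
    start_year: int,
    start_month: Optional[int],
    start_day: Optional[int],
    end_year: int,
    end_month: Optional[int],
    end_day: Optional[int],
) -> DateInterval:
    """Build a :class:`DateInterval` from possibly-partial calendar parts.

    The resolution is the finest part present on *both* ends; the start is
    snapped to the earliest possible day and the end to the latest
    possible day at that resolution.  Sampling "between June and August
    of 2007" therefore becomes [2007-06-01, 2007-08-31] at month
    resolution.

    Raises ``ValueError`` for impossible calendar parts or a start after
    the end.
    """
    if start_month is not None and start_day is not None and end_month is not None and end_day is not None:
        resolution = "day"
    elif start_month is not None and end_month is not None:
        resolution = "month"
    else:
        resolution = "year"

    def _snap(year: int, month: Optional[int], day: Optional[int], *, end: bool) -> _dt.date:
        if resolution == "year":
            return _dt.date(year, 12, 31) if end else _dt.date(year, 1, 1)
        assert month is not None
        if not 1 <= month <= 12:
            raise ValueError(f"month {month} out of range")
        if resolution == "month":
            last = calendar.monthrange(year, month)[1]
            return _dt.date(year, month, last if end else 1)
        assert day is not None
        return _dt.date(year, month, day)  # raises for e.g. 32nd January

    start = _snap(start_year, start_month, start_day, end=False)
    end = _snap(end_year, end_month, end_day, end=True)
    if start > end:
        raise ValueError(f"interval start {start} after end {end}")
    return DateInterval(start, end, resolution)


_RANGE_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*(?:-|--|–|—|\bto\b)\s*(\d+(?:\.\d+)?)\s*(?:years?)?\s*$",
    re.IGNORECASE,
)
_OPEN_RE = re.compile(
    r"^\s*(?:greater than|at least|more than|>=?|over)\s*(\d+(?:\.\d+)?)\s*(?:years?)?\s*$",
    re.IGNORECASE,
)
_PLAIN_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:years?)?\s*$", re.IGNORECASE)

#: Multiplier applied to open-ended reports ("at least N years" -> N * 1.25).
OPEN_ENDED_FACTOR = 1.25


def parse_time_since_conversion(text: str) -> float:
    """Parse a reported time since land-use conversion into years.

    Plain numbers pass through; ranges ("10-20 years") store the
    mid-range value; open-ended reports ("greater than N" / "at least N")
    store N x 1.25.
    """
    m = _PLAIN_RE.match(text)
    if m:
        return float(m.group(1))
    m = _RANGE_RE.match(text)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        if hi < lo:
            raise ValueError(f"descending range in {text!r}")
        return (lo + hi) / 2.0
    m = _OPEN_RE.match(text)
    if m:
        return float(m.group(1)) * OPEN_ENDED_FACTOR
    raise ValueError(f"cannot parse time since conversion: {text!r}")


def near_miss_land_use(a: LandUse, b: LandUse) -> bool:
    """Whether two differing land-use assignments are a pre-specified near miss.

    The four near-miss cases: primary vegetation vs mature secondary;
    adjacent stages of secondary vegetation; indeterminate secondary vs
    any other secondary stage; and "Cannot decide" vs any other class.
    Symmetric; exact matches are not near misses.
    """
    if a == b:
        raise ValueError("near-miss relation is only defined for differing assignments")
    ca, cb = a.land_use, b.land_use
    if LandUseClass.CANNOT_DECIDE in (ca, cb):
        return True
    pair = {ca, cb}
    if pair == {LandUseClass.PRIMARY, LandUseClass.SECONDARY}:
        sec = a if ca is LandUseClass.SECONDARY else b
        return sec.stage is SecondaryStage.MATURE
    if ca is LandUseClass.SECONDARY and cb is LandUseClass.SECONDARY:
        if SecondaryStage.INDETERMINATE in (a.stage, b.stage):
            return True
        return abs(_STAGE_ORDER[a.stage] - _STAGE_ORDER[b.stage]) == 1
    return False


def near_miss_intensity(a: UseIntensity, b: UseIntensity) -> bool:
    """Near-miss relation for use intensity: adjacent classes, or
    "Cannot decide" vs any other class."""
    if a == b:
        raise ValueError("near-miss relation is only defined for differing assignments")
    if UseIntensity.CANNOT_DECIDE in (a, b):
        return True
    return abs(_INTENSITY_ORDER[a] - _INTENSITY_ORDER[b]) == 1


def all_land_uses() -> Tuple[LandUse, ...]:
    """Every valid land-use assignment (secondary expanded by stage)."""
    out = []
    for c in LandUseClass:
        if c is LandUseClass.SECONDARY:
            out.extend(LandUse(c, s) for s in SecondaryStage)
        else:
            out.append(LandUse(c))
    return tuple(out)


def max_linear_extent(points: Sequence[Tuple[float, float]]) -> float:
    """Maximum linear extent, in meters, of a sampling geometry.

    ``points`` are (latitude, longitude) pairs in decimal degrees: the two
    ends of a transect, trap locations, or the vertices of a more complex
    design.  Returns the maximum pairwise great-circle distance (0 for a
    single point).
    """
    pts = list(points)
    if not pts:
        raise ValueError("at least one point required")
    if len(pts) == 1:
        return 0.0
    return max(
        great_circle_m(a[0], a[1], b[0], b[1]) for a, b in itertools.combinations(pts, 2)
    )
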