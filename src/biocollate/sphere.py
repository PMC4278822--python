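"""Spherical-earth distance and area primitives.

All geographic computations in this package assume a sphere of radius
6,371.0088 km (the IUGG mean Earth radius).  Coordinates are decimal
degrees on WGS84; treating them as spherical coordinates introduces a
relative error well below the 0.1-0.5% tolerances the geographic
operations document.
"""

from __future__ import annotations

import math

EARTH_RADIUS_KM = 6371.0088
EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0


def great_circle_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters between two lat/lon points (degrees).

    Uses the haversine formula, which is numerically stable for the short
    distances (site extents, offshore offsets) this package deals in.
    """
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def cell_area_km2(lat_south: float, lat_north: float, lon_width_deg: float) -> float:
    """Area in km^2 of a longitude-latitude cell on the sphere.

    Spherical-band formula: R^2 * dlambda * (sin phi_n - sin phi_s).
    Exact on the sphere, so summed cells conserve total area to rounding.
    """
    if lat_north < lat_south:
        raise ValueError("lat_north must be >= lat_south")
    dlam = math.radians(lon_width_deg)
    return (
        EARTH_RADIUS_KM**2
        * dlam
        * (math.sin(math.radians(lat_north)) - math.sin(math.radians(lat_south)))
    )
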