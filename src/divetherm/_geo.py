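"""Great-circle geometry helpers on a spherical Earth."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius
M_PER_DEG_LAT = 111_320.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Inputs broadcast like numpy arrays; scalars return a scalar float.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def meters_to_degrees(north_m: float, east_m: float, lat: float) -> tuple[float, float]:
    """Convert a small (north, east) displacement in meters to (dlat, dlon) degrees."""
    dlat = north_m / M_PER_DEG_LAT
    dlon = east_m / (M_PER_DEG_LAT * max(np.cos(np.radians(lat)), 1e-6))
    return dlat, dlon
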