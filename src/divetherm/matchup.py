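"""Collocate decoded dive profiles with a gridded daily model product.

Each profile is matched to the nearest sea grid cell (great-circle distance)
and to the daily model slice containing its mid-dive time. Profiles sharing a
(cell, date) are pooled: temperatures at identical depths are averaged and the
union of depths forms one merged observed profile, which is then linearly
interpolated onto the model's vertical levels — only levels inside the
observed depth span (no extrapolation). Every resulting observed/modeled pair
carries season, depth-range and sub-region labels for stratified statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._geo import haversine_km
from .decoder import DiveProfile
from .fields import GriddedField
from .regions import RegionSet

logger = logging.getLogger(__name__)

SEASONS = ("winter", "spring", "summer", "autumn")

#: Depth-range strata (m), half-open bins (lo, hi]; deeper than 100 m excluded.
DEPTH_RANGE_EDGES = (0.0, 15.0, 30.0, 50.0, 100.0)
DEPTH_RANGE_LABELS = ("0-15", "15-30", "30-50", "50-100")

PAIRS_COLUMNS = [
    "tag_id", "dive_id", "date", "lat", "lon", "depth_level",
    "obs_temp", "model_temp", "season", "depth_range", "subregion", "n_merged",
]


def assign_season(date) -> str:
    """Meteorological season: DJF winter, MAM spring, JJA summer, SON autumn."""
    month = pd.Timestamp(date).month
    return SEASONS[(month % 12) // 3]


def assign_depth_range(depth: float) -> str | None:
    """Depth-range stratum for a model level; None beyond 100 m (excluded)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    for lo, hi, label in zip(DEPTH_RANGE_EDGES[:-1], DEPTH_RANGE_EDGES[1:], DEPTH_RANGE_LABELS):
        if lo < depth <= hi:
            return label
    return None


def assign_subregion(lat: float, lon: float, regions: RegionSet) -> str:
    return regions.assign(lat, lon)


def match_profile_to_grid(
    profile: DiveProfile, field: GriddedField, max_dist_km: float = 25.0
) -> tuple[int, int, int] | None:
    """Nearest-sea-cell and daily-slice indices ``(iy, ix, it)`` for a profile.

    The cell is the water cell whose center minimizes great-circle distance to
    the fix position; equidistant candidates break to the lowest (lat-index,
    lon-index). The time index is the daily slice whose calendar date contains
    the mid-dive timestamp. Returns None (logged) when the position falls
    outside the field's dates or farther than ``max_dist_km`` from any sea
    cell.
    """
    lats, lons = field.lats, field.lons
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    d = haversine_km(profile.lat, profile.lon, glat, glon)
    d = np.where(field.sea_mask(), d, np.inf)
    dmin = d.min()
    if not np.isfinite(dmin) or dmin > max_dist_km:
        logger.info("profile %s unmatched: nearest sea cell %.1f km away", profile.dive_id, dmin)
        return None
    # tolerance so symmetric ties resolve to the lowest (iy, ix) in C order
    flat = np.flatnonzero(d <= dmin * (1 + 1e-12) + 1e-12)
    iy, ix = np.unravel_index(flat[0], d.shape)
    date = np.datetime64(profile.mid_time.date())
    hits = np.flatnonzero(field.dates == date)
    if hits.size == 0:
        logger.info("profile %s unmatched: date %s outside field time axis", profile.dive_id, date)
        return None
    return int(iy), int(ix), int(hits[0])


def _merge_observed(profiles: list[DiveProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Pool samples of co-located profiles: average temperatures at identical
    depths, union of depths otherwise; returns (depths, temps) sorted by depth."""
    pts: dict[float, list[float]] = {}
    for p in profiles:
        for _, z, t in p.samples:
            pts.setdefault(z, []).append(t)
    depths = np.array(sorted(pts))
    temps = np.array([np.mean(pts[z]) for z in depths])
    return depths, temps


def collocate(
    profiles: list[DiveProfile],
    field: GriddedField,
    regions: RegionSet | None = None,
    max_dist_km: float = 25.0,
    single_sample_tol_m: float = 2.5,
) -> pd.DataFrame:
    """Build the matched observed/modeled pair table.

    A merged observed profile that collapses to a single depth contributes
    only at model levels within ``single_sample_tol_m`` of that depth.
    Pairs at model levels deeper than 100 m keep ``depth_range`` = NA and are
    excluded from depth-stratified analyses downstream.
    """
    regions = regions or RegionSet.default()
    groups: dict[tuple[int, int, int], list[DiveProfile]] = {}
    n_unmatched = 0
    for p in profiles:
        key = match_profile_to_grid(p, field, max_dist_km=max_dist_km)
        if key is None:
            n_unmatched += 1
            continue
        groups.setdefault(key, []).append(p)
    if n_unmatched:
        logger.info("collocate: %d profiles unmatched", n_unmatched)

    levels = field.depths
    values = field.values
    rows = []
    for (iy, ix, it), grp in sorted(groups.items()):
        grp = sorted(grp, key=lambda p: (p.tag_id, p.fix_utc))
        depths, temps = _merge_observed(grp)
        if depths.size == 1:
            sel = np.abs(levels - depths[0]) <= single_sample_tol_m
            if not sel.any():
                logger.debug("single-sample group at (%d,%d,%d) dropped: no level within tolerance", iy, ix, it)
                continue
            obs = np.full(levels.shape, temps[0])
        else:
            sel = (levels >= depths[0]) & (levels <= depths[-1])
            obs = np.interp(levels, depths, temps)
        cell_lat, cell_lon = float(field.lats[iy]), float(field.lons[ix])
        date = pd.Timestamp(field.times[it]).date()
        season = assign_season(date)
        subregion = assign_subregion(cell_lat, cell_lon, regions)
        lead = grp[0]
        for iz in np.flatnonzero(sel):
            model_t = values[it, iz, iy, ix]
            if not np.isfinite(model_t):
                continue
            rows.append(
                (
                    lead.tag_id, lead.dive_id, date.isoformat(), cell_lat, cell_lon,
                    float(levels[iz]), float(obs[iz]), float(model_t), season,
                    assign_depth_range(float(levels[iz])), subregion, len(grp),
                )
            )
    return pd.DataFrame(rows, columns=PAIRS_COLUMNS)
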