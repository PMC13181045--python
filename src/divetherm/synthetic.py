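"""Known-truth synthetic data: ocean field, model product, turtle dives, ARGO.

Everything downstream of the tag decoder is testable against this module
because the seawater temperature is a closed-form function of depth, date and
latitude: a logistic thermocline whose surface temperature and mixed-layer
depth oscillate seasonally. The "model product" is that truth sampled on a
regular grid plus a systematic depth-dependent bias and white noise, emulating
an operational analysis product. Turtle dives are trapezoidal depth excursions
sampled every 5 minutes, encoded into the tag CSV dialect the decoder parses.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geo import meters_to_degrees
from .fields import GriddedField
from .params import (
    ArgoSimParams,
    Bbox,
    ModelProductParams,
    OceanTruthParams,
    TurtleSimParams,
    date_range,
)

logger = logging.getLogger(__name__)

#: Isotropic Argos position-error standard deviations (m) by location quality.
LQ_ERROR_SD_M = {"3": 250.0, "2": 500.0, "1": 1000.0, "0": 1500.0, "A": 3000.0, "B": 5000.0, "Z": 10000.0}

TAG_FILE_COLUMNS = (
    ["tag_id", "row_type", "utc", "lat", "lon", "lq", "sst", "sst_time_min"]
    + [f"{k}{i}" for i in range(1, 7) for k in ("d", "t")]
    + ["dt_time_min"]
)


def _doy(date: dt.date) -> int:
    if isinstance(date, dt.datetime):
        date = date.date()
    return date.timetuple().tm_yday


def surface_temperature(date: dt.date, lat, params: OceanTruthParams):
    """Seasonal surface temperature with an optional latitudinal gradient (°C)."""
    phase = 2.0 * math.pi * (_doy(date) - params.peak_doy) / 365.25
    return params.t_mean + params.a_surf * math.cos(phase) + params.lat_gradient * (np.asarray(lat) - params.lat_ref)


def mixed_layer_depth(date: dt.date, params: OceanTruthParams) -> float:
    """Mixed-layer depth (m), shallowest at the surface-temperature peak."""
    phase = 2.0 * math.pi * (_doy(date) - params.peak_doy) / 365.25
    mean = 0.5 * (params.mld_winter + params.mld_summer)
    amp = 0.5 * (params.mld_winter - params.mld_summer)
    return mean - amp * math.cos(phase)


def truth_temperature(depth, date: dt.date, lat, params: OceanTruthParams):
    """True seawater temperature (°C) at depth (m), calendar date and latitude.

    T(z) = T_deep + (T_surf − T_deep) / (1 + exp((z − MLD)/w_thermo)).
    Broadcasts over array-like ``depth`` and ``lat``.
    """
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    t_surf = surface_temperature(date, lat, params)
    mld = mixed_layer_depth(date, params)
    s = 1.0 / (1.0 + np.exp((z - mld) / params.w_thermo))
    out = params.t_deep + (t_surf - params.t_deep) * s
    if out.ndim == 0:
        return float(out)
    return out


def generate_model_field(
    truth: OceanTruthParams,
    product: ModelProductParams,
    dates: list[dt.date],
    bbox: Bbox,
    land_mask=None,
) -> GriddedField:
    """Gridded daily product: truth at cell centers + bias_profile(z) + noise.

    ``land_mask`` is an optional boolean (lat, lon) array, True over land
    (those cells become NaN at all times and depths).
    """
    if not dates:
        raise ValueError("empty date range")
    step = product.grid_step
    lats = np.arange(bbox.lat_min + step / 2.0, bbox.lat_max, step)
    lons = np.arange(bbox.lon_min + step / 2.0, bbox.lon_max, step)
    if lats.size == 0 or lons.size == 0:
        raise ValueError("bounding box smaller than one grid cell")
    depths = np.asarray(product.depth_levels, dtype=float)
    bias = product.bias_array()

    values = np.empty((len(dates), depths.size, lats.size, lons.size))
    for it, date in enumerate(dates):
        # truth is independent of longitude; broadcast (Z, Y) → (Z, Y, X)
        prof = truth_temperature(depths[:, None], date, lats[None, :], truth)
        values[it] = prof[:, :, None] + bias[:, None, None]
    if product.noise_sd > 0:
        rng = np.random.default_rng(product.seed)
        values += rng.normal(0.0, product.noise_sd, size=values.shape)
    if land_mask is not None:
        values[:, :, np.asarray(land_mask, dtype=bool)] = np.nan
    times = [dt.datetime.combine(d, dt.time(12, 0)) for d in dates]
    return GriddedField.from_arrays(values, times, depths, lats, lons)


@dataclass
class SimulatedDive:
    """One dive with its ground truth and the post-dive Argos fix."""

    tag_id: str
    dive_index: int
    samples: list[tuple[dt.datetime, float, float]]  # (utc, depth m, temp °C)
    true_lat: float
    true_lon: float
    fix_utc: dt.datetime
    fix_lat: float
    fix_lon: float
    lq: str
    sst: float
    sst_time_min: int
    extras: dict = field(default_factory=dict)

    @property
    def max_depth(self) -> float:
        return max(d for _, d, _ in self.samples)

    @property
    def duration_min(self) -> float:
        return (self.samples[-1][0] - self.samples[0][0]).total_seconds() / 60.0


def _dive_depth_sequence(max_depth: float, params: TurtleSimParams) -> list[float]:
    """Trapezoidal descent–bottom–ascent depths, one value per 5-min sample."""
    step = params.descent_rate_m_per_min * params.sample_interval_min
    n_desc = max(1, math.ceil(max_depth / step))
    max_samples = params.duration_cap_min // params.sample_interval_min
    zero = 1 if params.include_surface_zero else 0
    budget = max_samples - (2 * n_desc - 1) - zero
    f = params.bottom_fraction
    n_bot = max(1, int(round(2 * n_desc * f / max(1.0 - f, 1e-9))))
    n_bot = max(1, min(n_bot, budget))
    down = [max_depth * k / n_desc for k in range(1, n_desc + 1)]
    bottom = [max_depth] * n_bot
    up = [max_depth * (n_desc - k) / n_desc for k in range(1, n_desc)]
    seq = down + bottom + up
    if params.include_surface_zero:
        seq.append(0.0)
    return seq


def _draw_max_depth(rng: np.random.Generator, params: TurtleSimParams) -> float:
    step = params.descent_rate_m_per_min * params.sample_interval_min
    max_samples = params.duration_cap_min // params.sample_interval_min
    zero = 1 if params.include_surface_zero else 0
    # deepest dive whose trapezoid (≥1 bottom sample) fits the duration cap
    feasible = step * ((max_samples - zero - 1) // 2)
    cap = min(params.depth_cap_m, feasible)
    for _ in range(1000):
        d = params.depth_min_m + rng.exponential(params.depth_scale_m)
        if d <= cap:
            return d
    return cap


def simulate_turtle_dives(
    params: TurtleSimParams,
    truth: OceanTruthParams,
    dates: list[dt.date],
    bbox: Bbox | None = None,
    domain: Bbox | None = None,
) -> list[SimulatedDive]:
    """Simulate turtles random-walking inside ``bbox``, diving on a schedule
    spread evenly across ``dates``, each dive fully inside one calendar day.

    Every sample lies on a 5-min lattice, depths never exceed the 175-m cap and
    durations never exceed 240 min. Each dive ends with an Argos fix whose
    location-quality class is drawn from ``lq_probabilities`` and whose
    position is the true position plus an isotropic class-dependent error
    (1,500 m s.d. for LQ 0 by default).
    """
    if not dates:
        raise ValueError("empty date range")
    bbox = bbox or Bbox()
    if domain is not None and not (
        domain.lat_min <= bbox.lat_min <= bbox.lat_max <= domain.lat_max
        and domain.lon_min <= bbox.lon_min <= bbox.lon_max <= domain.lon_max
    ):
        raise ValueError("turtle bbox extends outside the field domain")
    rng = np.random.default_rng(params.seed)
    lq_classes = list(params.lq_probabilities)
    lq_probs = np.array([params.lq_probabilities[c] for c in lq_classes])
    margin_lat = 0.02 * (bbox.lat_max - bbox.lat_min)
    margin_lon = 0.02 * (bbox.lon_max - bbox.lon_min)

    n_slots = math.ceil(params.n_dives_per_turtle / params.dives_per_day)
    window_min = 1440 // params.dives_per_day

    dives: list[SimulatedDive] = []
    for it in range(params.n_turtles):
        tag_id = f"TAG{it + 1:03d}"
        lat = rng.uniform(bbox.lat_min + margin_lat, bbox.lat_max - margin_lat)
        lon = rng.uniform(bbox.lon_min + margin_lon, bbox.lon_max - margin_lon)
        prev_day = None
        for idive in range(params.n_dives_per_turtle):
            slot = idive // params.dives_per_day
            frac = slot / max(n_slots - 1, 1)
            date = dates[int(round(frac * (len(dates) - 1)))]
            if date != prev_day:  # daily random-walk displacement
                lat += rng.normal(0.0, params.rw_step_deg)
                lon += rng.normal(0.0, params.rw_step_deg)
                lat = float(np.clip(lat, bbox.lat_min + margin_lat, bbox.lat_max - margin_lat))
                lon = float(np.clip(lon, bbox.lon_min + margin_lon, bbox.lon_max - margin_lon))
                prev_day = date
            true_lat = float(np.clip(lat + rng.normal(0, 0.005), bbox.lat_min, bbox.lat_max))
            true_lon = float(np.clip(lon + rng.normal(0, 0.005), bbox.lon_min, bbox.lon_max))

            max_depth = _draw_max_depth(rng, params)
            depths = _dive_depth_sequence(max_depth, params)
            j = idive % params.dives_per_day
            # start inside the day's j-th window, leaving room for the dive
            # plus the transmission delay before the window (and day) ends
            start_min = j * window_min + 15
            t0 = dt.datetime.combine(date, dt.time(0, 0)) + dt.timedelta(minutes=start_min)
            samples = []
            for k, z in enumerate(depths, start=1):
                ts = t0 + dt.timedelta(minutes=params.sample_interval_min * k)
                temp = truth_temperature(z, date, true_lat, truth)
                if params.temp_noise_sd > 0:
                    temp += rng.normal(0.0, params.temp_noise_sd)
                samples.append((ts, float(z), float(temp)))

            if rng.random() >= params.transmission_success_prob:
                continue
            lq = str(rng.choice(lq_classes, p=lq_probs))
            sd = params.lq0_position_error_sd_m if lq == "0" else LQ_ERROR_SD_M.get(lq, 1500.0)
            dlat, dlon = meters_to_degrees(rng.normal(0, sd), rng.normal(0, sd), true_lat)
            fix_utc = samples[-1][0] + dt.timedelta(minutes=params.transmission_delay_min)
            sst = float(truth_temperature(0.5, date, true_lat, truth))
            if params.temp_noise_sd > 0:
                sst += float(rng.normal(0.0, params.temp_noise_sd))
            sst_time = int((fix_utc - t0).total_seconds() // 60)
            dives.append(
                SimulatedDive(
                    tag_id=tag_id,
                    dive_index=idive,
                    samples=samples,
                    true_lat=true_lat,
                    true_lon=true_lon,
                    fix_utc=fix_utc,
                    fix_lat=true_lat + dlat,
                    fix_lon=true_lon + dlon,
                    lq=lq,
                    sst=sst,
                    sst_time_min=sst_time,
                )
            )
    return dives


def _fmt(x: float) -> str:
    return repr(float(x))


def encode_tag_file(dives: list[SimulatedDive], path, diag_every: int = 0) -> None:
    """Write dives to the tag CSV dialect (one file, any number of tags).

    Per dive: one FIX row, then its DIVE rows most-recent-record-first
    (increasing DTtime). Samples are split chronologically into 30-min blocks
    of up to six depth–temperature pairs; within a row pairs are chronological,
    the most recent sample occupying the last populated slot. Every DIVE row
    repeats the dive's SST and SSTtime; DTtime is the integer number of
    minutes between the row's most recent sample and the transmission time.
    ``diag_every`` > 0 interleaves a DIAG row after every that many dives.
    """
    dives = sorted(dives, key=lambda d: (d.tag_id, d.fix_utc))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TAG_FILE_COLUMNS)
        for n, dive in enumerate(dives, start=1):
            w.writerow(
                [dive.tag_id, "FIX", dive.fix_utc.isoformat(), _fmt(dive.fix_lat), _fmt(dive.fix_lon), dive.lq]
                + [""] * 14
                + [""]
            )
            blocks = [dive.samples[i : i + 6] for i in range(0, len(dive.samples), 6)]
            for block in reversed(blocks):  # most recent record first
                dt_min = int((dive.fix_utc - block[-1][0]).total_seconds() // 60)
                pairs: list[str] = []
                for _, z, temp in block:
                    pairs += [_fmt(z), _fmt(temp)]
                pairs += [""] * (12 - len(pairs))
                w.writerow(
                    [dive.tag_id, "DIVE", "", "", "", "", _fmt(dive.sst), str(dive.sst_time_min)]
                    + pairs
                    + [str(dt_min)]
                )
            if diag_every > 0 and n % diag_every == 0:
                w.writerow([dive.tag_id, "DIAG"] + [""] * (len(TAG_FILE_COLUMNS) - 2))
    logger.info("wrote %d dives to %s", len(dives), path)


def write_tag_files(dives: list[SimulatedDive], out_dir, diag_every: int = 0) -> list[str]:
    """One tag CSV per tag id under ``out_dir``; returns the paths written."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    by_tag: dict[str, list[SimulatedDive]] = {}
    for d in dives:
        by_tag.setdefault(d.tag_id, []).append(d)
    for tag_id in sorted(by_tag):
        p = out_dir / f"{tag_id}.csv"
        encode_tag_file(by_tag[tag_id], p, diag_every=diag_every)
        paths.append(str(p))
    return paths


def simulate_argo_profiles(
    params: ArgoSimParams,
    truth: OceanTruthParams,
    dates: list[dt.date],
    bbox: Bbox | None = None,
) -> pd.DataFrame:
    """ARGO-style profiles: truth at 1-m depth resolution + independent noise.

    Returns a long table ``platform_id, utc, lat, lon, depth_m, temp_c`` with
    exactly ``n_profiles`` distinct (platform, time) casts at noon of randomly
    chosen days, positions uniform in ``bbox``.
    """
    if not dates:
        raise ValueError("empty date range")
    bbox = bbox or Bbox()
    rng = np.random.default_rng(params.seed)
    platforms = params.platform_ids or [f"ARGO{i + 1:03d}" for i in range(3)]
    depths = np.arange(0.0, params.max_depth_m + 0.5, 1.0)
    rows = []
    for i in range(params.n_profiles):
        pid = platforms[i % len(platforms)]
        date = dates[int(rng.integers(len(dates)))]
        utc = dt.datetime.combine(date, dt.time(12, 0)) + dt.timedelta(minutes=int(rng.integers(0, 60)))
        lat = rng.uniform(bbox.lat_min, bbox.lat_max)
        lon = rng.uniform(bbox.lon_min, bbox.lon_max)
        temps = truth_temperature(depths, date, lat, truth)
        if params.noise_sd > 0:
            temps = temps + rng.normal(0.0, params.noise_sd, size=depths.shape)
        for z, t in zip(depths, temps):
            rows.append((pid, utc.isoformat(), lat, lon, float(z), float(t)))
    return pd.DataFrame(rows, columns=["platform_id", "utc", "lat", "lon", "depth_m", "temp_c"])


__all__ = [
    "surface_temperature",
    "mixed_layer_depth",
    "truth_temperature",
    "generate_model_field",
    "SimulatedDive",
    "simulate_turtle_dives",
    "encode_tag_file",
    "write_tag_files",
    "simulate_argo_profiles",
    "date_range",
    "TAG_FILE_COLUMNS",
]
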