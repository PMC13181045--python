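"""Parameter models for the synthetic ocean, model product and tag simulators.

All parameter containers are pydantic models with ``extra="forbid"`` so that a
misspelled key in a YAML configuration is rejected with a message naming the
offending key rather than silently ignored.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Hard physical/firmware limits of the emulated tag.
MAX_DIVE_DEPTH_M = 175.0
MAX_DIVE_DURATION_MIN = 240
SAMPLE_INTERVAL_MIN = 5
RECORD_BLOCK_MIN = 30  # one stored record covers 30 min (6 samples at 5 min)

#: Argos location-quality classes, worst to best.
LQ_CLASSES = ("Z", "B", "A", "0", "1", "2", "3")


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class Bbox(_Params):
    """Geographic bounding box in decimal degrees."""

    lat_min: float = 41.0
    lat_max: float = 42.5
    lon_min: float = 16.0
    lon_max: float = 18.0

    @model_validator(mode="after")
    def _non_degenerate(self):
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("bounding box is degenerate (max must exceed min)")
        return self

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.lat_min + self.lat_max), 0.5 * (self.lon_min + self.lon_max))

    def contains(self, lat: float, lon: float) -> bool:
        return self.lat_min <= lat <= self.lat_max and self.lon_min <= lon <= self.lon_max


class OceanTruthParams(_Params):
    """Known-truth thermal structure: seasonal surface forcing over a logistic
    thermocline.

    T(z, t, φ) = T_deep + (T_surf(t, φ) − T_deep) · s(z),
    s(z) = 1 / (1 + exp((z − MLD(t)) / w_thermo)),
    T_surf(t, φ) = T_mean + A_surf · cos(2π (doy − peak_doy)/365.25)
                   + lat_gradient · (φ − lat_ref),
    with the mixed-layer depth MLD(t) oscillating between its winter and summer
    extremes in antiphase with the surface temperature.
    """

    t_deep: float = 13.0  # °C, abyssal temperature
    t_mean: float = 19.0  # °C, annual-mean surface temperature
    a_surf: float = 6.0  # °C, seasonal surface amplitude
    peak_doy: float = 225.0  # day of year of the surface temperature maximum
    mld_winter: float = Field(70.0, gt=0)  # m
    mld_summer: float = Field(15.0, gt=0)  # m
    w_thermo: float = Field(10.0, gt=0)  # m, thermocline half-width
    lat_gradient: float = -0.1  # °C per degree latitude
    lat_ref: float = 41.5  # latitude where the gradient term vanishes


class ModelProductParams(_Params):
    """Gridded model product = truth + systematic depth-dependent bias + noise."""

    grid_step: float = Field(1.0 / 24.0, gt=0)  # degrees
    depth_levels: list[float] = Field(
        default_factory=lambda: [float(z) for z in range(1, 31, 2)]
        + [float(z) for z in range(35, 121, 5)]
    )
    bias_profile: float | list[float] = 0.2  # °C; scalar or one value per level
    noise_sd: float = Field(0.1, ge=0)  # °C
    seed: int = Field(0, ge=0, lt=2**31)

    @field_validator("depth_levels")
    @classmethod
    def _increasing(cls, v):
        arr = np.asarray(v, dtype=float)
        if arr.size == 0 or np.any(np.diff(arr) <= 0):
            raise ValueError("depth_levels must be non-empty and strictly increasing")
        return [float(z) for z in arr]

    @model_validator(mode="after")
    def _bias_len(self):
        if isinstance(self.bias_profile, list) and len(self.bias_profile) != len(self.depth_levels):
            raise ValueError("bias_profile list must have one entry per depth level")
        return self

    def bias_array(self) -> np.ndarray:
        if isinstance(self.bias_profile, list):
            return np.asarray(self.bias_profile, dtype=float)
        return np.full(len(self.depth_levels), float(self.bias_profile))


class TurtleSimParams(_Params):
    """Simulated turtle behaviour and tag characteristics.

    Dive depths follow an exponential distribution (scale ``depth_scale_m``)
    right-truncated at ``depth_cap_m``; the vertical excursion per 5-min sample
    is bounded by ``descent_rate_m_per_min`` so reconstructed profiles resolve
    the thermocline, which together with the 240-min duration cap bounds the
    deepest feasible dive.
    """

    n_turtles: int = Field(7, gt=0)
    n_dives_per_turtle: int = Field(40, gt=0)
    dives_per_day: int = Field(3, gt=0, le=5)
    depth_scale_m: float = Field(30.0, gt=0)
    depth_min_m: float = Field(5.0, gt=0)
    depth_cap_m: float = Field(MAX_DIVE_DEPTH_M, gt=0, le=MAX_DIVE_DEPTH_M)
    duration_cap_min: int = Field(MAX_DIVE_DURATION_MIN, gt=0, le=MAX_DIVE_DURATION_MIN)
    sample_interval_min: int = Field(SAMPLE_INTERVAL_MIN, gt=0)
    bottom_fraction: float = Field(0.3, ge=0.0, le=0.8)
    descent_rate_m_per_min: float = Field(1.0, gt=0)
    lq_probabilities: dict[str, float] = Field(
        default_factory=lambda: {"Z": 0.05, "B": 0.10, "A": 0.10, "0": 0.50, "1": 0.10, "2": 0.10, "3": 0.05}
    )
    lq0_position_error_sd_m: float = Field(1500.0, ge=0)
    transmission_delay_min: int = Field(10, ge=0)
    transmission_success_prob: float = Field(1.0, ge=0.0, le=1.0)
    temp_noise_sd: float = Field(0.05, ge=0)  # °C, sensor noise
    include_surface_zero: bool = True  # append a 0-m surfacing sample per dive
    rw_step_deg: float = Field(0.05, ge=0)  # daily random-walk step
    seed: int = Field(0, ge=0, lt=2**31)

    @field_validator("sample_interval_min")
    @classmethod
    def _divides_block(cls, v):
        if RECORD_BLOCK_MIN % v != 0:
            raise ValueError(f"sample_interval_min must divide {RECORD_BLOCK_MIN}")
        return v

    @field_validator("lq_probabilities")
    @classmethod
    def _valid_lq(cls, v):
        unknown = set(v) - set(LQ_CLASSES)
        if unknown:
            raise ValueError(f"unknown LQ classes: {sorted(unknown)}")
        total = sum(v.values())
        if total <= 0 or any(p < 0 for p in v.values()):
            raise ValueError("lq_probabilities must be non-negative with positive total")
        return {k: p / total for k, p in v.items()}


class ArgoSimParams(_Params):
    """Synthetic ARGO-style floats: 1-m resolution profiles of truth + noise.

    Defaults emulate three platforms cycling roughly every nine days over a
    year (~40 casts each).
    """

    n_profiles: int = Field(120, gt=0)
    max_depth_m: float = Field(50.0, gt=0)
    noise_sd: float = Field(0.05, ge=0)  # °C
    platform_ids: list[str] | None = None
    seed: int = Field(0, ge=0, lt=2**31)


def date_range(start: dt.date, end: dt.date) -> list[dt.date]:
    """Inclusive list of calendar days."""
    if end < start:
        raise ValueError("empty date range: end precedes start")
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
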