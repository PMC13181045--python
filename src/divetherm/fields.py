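"""Gridded 4-D temperature fields (time × depth × lat × lon).

Thin wrapper over an :class:`xarray.Dataset` holding a CF-style daily
temperature variable ``thetao`` (°C). Files are netCDF3 classic, written and
read with xarray's scipy backend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

VAR_NAME = "thetao"


@dataclass
class GriddedField:
    """Daily 4-D temperature field with axes (time, depth, lat, lon)."""

    ds: xr.Dataset

    def __post_init__(self):
        if VAR_NAME not in self.ds:
            raise ValueError(f"dataset lacks variable {VAR_NAME!r}")
        for dim in ("time", "depth", "lat", "lon"):
            if dim not in self.ds[VAR_NAME].dims:
                raise ValueError(f"variable {VAR_NAME!r} lacks dimension {dim!r}")
        for ax in ("depth", "lat", "lon"):
            vals = self.ds[ax].values
            if vals.size > 1 and not (np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0)):
                raise ValueError(f"axis {ax!r} is not strictly monotone")

    @property
    def values(self) -> np.ndarray:
        return self.ds[VAR_NAME].values

    @property
    def times(self) -> np.ndarray:
        return self.ds["time"].values

    @property
    def dates(self) -> np.ndarray:
        return self.ds["time"].values.astype("datetime64[D]")

    @property
    def depths(self) -> np.ndarray:
        return self.ds["depth"].values

    @property
    def lats(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.ds["lon"].values

    def sea_mask(self) -> np.ndarray:
        """Boolean (lat, lon) mask of water cells: finite at the top level of
        the first time slice."""
        return np.isfinite(self.values[0, 0, :, :])

    def to_netcdf(self, path: str | Path) -> None:
        enc = {VAR_NAME: {"dtype": "f8"}}
        self.ds.to_netcdf(str(path), engine="scipy", encoding=enc)

    @classmethod
    def open(cls, path: str | Path) -> "GriddedField":
        ds = xr.open_dataset(str(path), engine="scipy").load()
        return cls(ds)

    @classmethod
    def from_arrays(cls, values, times, depths, lats, lons) -> "GriddedField":
        ds = xr.Dataset(
            {VAR_NAME: (("time", "depth", "lat", "lon"), np.asarray(values, dtype=float))},
            coords={
                "time": pd.to_datetime(times),
                "depth": np.asarray(depths, dtype=float),
                "lat": np.asarray(lats, dtype=float),
                "lon": np.asarray(lons, dtype=float),
            },
        )
        ds[VAR_NAME].attrs.update(units="degC", standard_name="sea_water_potential_temperature")
        ds["depth"].attrs.update(units="m", positive="down")
        ds["lat"].attrs.update(units="degrees_north")
        ds["lon"].attrs.update(units="degrees_east")
        return cls(ds)
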