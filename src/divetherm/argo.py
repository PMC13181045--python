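"""Upper-ocean consistency check against ARGO-style float profiles.

Turtle-borne and float temperature samples are cross-paired when they fall in
the same 1-m depth bin, lie within 10 km of each other (great circle) and were
acquired within ±15 days. The per-bin BIAS (float minus turtle by default) is
then reported from the surface down to 12 m together with the number of
matched pairs per bin. One turtle sample may pair with several float samples;
no deduplication is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._geo import haversine_km

PAIRING_COLUMNS = [
    "turtle_utc", "turtle_lat", "turtle_lon", "turtle_depth", "turtle_temp",
    "platform_id", "argo_utc", "argo_lat", "argo_lon", "argo_depth", "argo_temp",
    "separation_km", "separation_days", "depth_bin",
]


def _depth_bin(depth: np.ndarray) -> np.ndarray:
    """1-m bins (0,1] → 0, (1,2] → 1, …; non-positive depths → −1 (excluded)."""
    d = np.asarray(depth, dtype=float)
    return np.where(d > 0, np.ceil(d).astype(int) - 1, -1)


def pair_argo_turtle(
    turtle: pd.DataFrame,
    argo: pd.DataFrame,
    max_dist_km: float = 10.0,
    max_days: float = 15.0,
) -> pd.DataFrame:
    """All turtle×float sample pairs in the same 1-m bin within both thresholds.

    ``turtle`` is the decoder's profile table (``utc, lat, lon, depth_m,
    temp_c`` columns); ``argo`` is the float table with the same columns plus
    ``platform_id``. Thresholds are inclusive. Empty results are allowed.
    """
    if turtle.empty or argo.empty:
        raise ValueError("both turtle and argo tables must be non-empty")
    t = turtle.copy()
    a = argo.copy()
    t["_bin"] = _depth_bin(t["depth_m"].values)
    a["_bin"] = _depth_bin(a["depth_m"].values)
    t = t[t["_bin"] >= 0]
    a = a[a["_bin"] >= 0]
    t["_utc"] = pd.to_datetime(t["utc"])
    a["_utc"] = pd.to_datetime(a["utc"])

    rows = []
    for b, tg in t.groupby("_bin"):
        ag = a[a["_bin"] == b]
        if ag.empty:
            continue
        dist = haversine_km(
            tg["lat"].values[:, None], tg["lon"].values[:, None],
            ag["lat"].values[None, :], ag["lon"].values[None, :],
        )
        ddays = (
            np.abs(tg["_utc"].values[:, None] - ag["_utc"].values[None, :])
            / np.timedelta64(1, "s") / 86400.0
        )
        ii, jj = np.nonzero((dist <= max_dist_km) & (ddays <= max_days))
        for i, j in zip(ii, jj):
            tr, ar = tg.iloc[i], ag.iloc[j]
            rows.append(
                (
                    tr["utc"], tr["lat"], tr["lon"], tr["depth_m"], tr["temp_c"],
                    ar["platform_id"], ar["utc"], ar["lat"], ar["lon"], ar["depth_m"], ar["temp_c"],
                    float(dist[i, j]), float(ddays[i, j]), int(b),
                )
            )
    return pd.DataFrame(rows, columns=PAIRING_COLUMNS)


def binned_bias(
    pairings: pd.DataFrame,
    dz: float = 1.0,
    zmax: float = 12.0,
    orientation: str = "argo_minus_turtle",
) -> pd.DataFrame:
    """Per-depth-bin BIAS and pair count from the surface down to ``zmax``.

    Bins are (0,1], …, (zmax−1, zmax]; empty bins are reported with N = 0 and
    NA BIAS. ``orientation`` flips the difference to ``turtle_minus_argo`` if
    desired.
    """
    n_bins = int(round(zmax / dz))
    sign = {"argo_minus_turtle": 1.0, "turtle_minus_argo": -1.0}[orientation]
    rows = []
    for b in range(n_bins):
        sel = pairings[pairings["depth_bin"] == b] if not pairings.empty else pairings
        n = len(sel)
        if n:
            bias_b = sign * float((sel["argo_temp"] - sel["turtle_temp"]).mean())
        else:
            bias_b = np.nan
        rows.append({"bin_top_m": b * dz, "bin_bottom_m": (b + 1) * dz, "n": n, "bias": bias_b})
    return pd.DataFrame(rows)
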