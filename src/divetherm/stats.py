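"""Validation statistics: Pearson r, BIAS, RMSE and unbiased RMSE.

Sign convention: BIAS = mean(model − observation), so a positive BIAS means
the model product is warmer than the observations. uRMSE = √(RMSE² − BIAS²)
is the residual error after removing the systematic offset; the identity
uRMSE² + BIAS² = RMSE² holds exactly for every summary row. Significance of r
uses the two-sided t transformation t = r·√((n−2)/(1−r²)) on n−2 degrees of
freedom.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

MIN_N = 3  # fewer pairs than this → metrics reported as NA

#: Default reporting rule used for the headline correlation table.
TABLE1_R_THRESHOLD = 0.6
TABLE1_P_THRESHOLD = 0.05


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation r = cov(x, y)/(σx σy) and its two-sided p-value.

    Implemented from the covariance formula (sample normalization, which
    cancels in the ratio); p from the t transformation on n − 2 d.o.f.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    n = x.size
    if n < MIN_N:
        raise ValueError(f"need at least {MIN_N} pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc) / (n - 1))
    sy = math.sqrt(float(yc @ yc) / (n - 1))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("undefined correlation: zero variance")
    r = float(xc @ yc) / ((n - 1) * sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p


def bias(obs, model) -> float:
    """Mean model-minus-observation difference (°C)."""
    obs = np.asarray(obs, dtype=float)
    model = np.asarray(model, dtype=float)
    if obs.size == 0 or obs.shape != model.shape:
        raise ValueError("series must be non-empty and of equal length")
    return float(np.mean(model - obs))


def error_metrics(obs, model) -> tuple[float, float, float]:
    """(BIAS, RMSE, uRMSE); uRMSE clamped at 0 against round-off negatives."""
    obs = np.asarray(obs, dtype=float)
    model = np.asarray(model, dtype=float)
    if obs.size == 0 or obs.shape != model.shape:
        raise ValueError("series must be non-empty and of equal length")
    diff = model - obs
    b = float(diff.mean())
    rmse = float(np.sqrt(np.mean(diff**2)))
    urmse = math.sqrt(max(rmse**2 - b**2, 0.0))
    return b, rmse, urmse


def _summary_row(g: pd.DataFrame) -> pd.Series:
    n = len(g)
    out = {
        "n_pairs": n,
        "n_dives": g["dive_id"].nunique() if "dive_id" in g else n,
        "r": np.nan,
        "p": np.nan,
        "bias": np.nan,
        "rmse": np.nan,
        "urmse": np.nan,
    }
    if n >= MIN_N:
        b, rmse, urmse = error_metrics(g["obs_temp"], g["model_temp"])
        out.update(bias=b, rmse=rmse, urmse=urmse)
        try:
            out["r"], out["p"] = pearson_r(g["obs_temp"], g["model_temp"])
        except ValueError:
            pass  # zero variance in a stratum: r stays NA
    return pd.Series(out)


def stratified_summary(pairs: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """One row per occupied stratum with N, r, p, BIAS, RMSE and uRMSE.

    ``by`` names label columns of the pair table (``season``, ``depth_range``,
    ``subregion``). Pairs lacking a label (e.g. levels deeper than 100 m when
    stratifying by depth range) are excluded from that grouping. Strata with
    fewer than 3 pairs keep their counts but carry NA metrics.
    """
    for col in by:
        if col not in pairs.columns:
            raise ValueError(f"pairs table lacks stratum column {col!r}")
    data = pairs.dropna(subset=by)
    if data.empty:
        return pd.DataFrame(columns=by + ["n_pairs", "n_dives", "r", "p", "bias", "rmse", "urmse"])
    out = (
        data.groupby(by, observed=True, dropna=True)
        .apply(_summary_row, include_groups=False)
        .reset_index()
    )
    out["n_pairs"] = out["n_pairs"].astype(int)
    out["n_dives"] = out["n_dives"].astype(int)
    return out


def table1_filter(
    summary: pd.DataFrame,
    r_threshold: float = TABLE1_R_THRESHOLD,
    p_threshold: float = TABLE1_P_THRESHOLD,
) -> pd.DataFrame:
    """Reporting rule for the headline table: keep strata with r > 0.6 that
    are statistically significant (p < 0.05); the full table is kept separately."""
    keep = (summary["r"] > r_threshold) & (summary["p"] < p_threshold)
    return summary[keep.fillna(False)].reset_index(drop=True)


def layer_profile_summary(pairs: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per (group, model depth level): mean obs, mean model, BIAS, uRMSE, N.

    ``group`` is ``"season"`` or ``"subregion"`` — vertical-profile summaries
    averaged within the grouping, one row per occupied model level.
    """
    if group not in pairs.columns:
        raise ValueError(f"pairs table lacks column {group!r}")
    rows = []
    for (gval, level), g in pairs.groupby([group, "depth_level"], observed=True):
        b, rmse, urmse = error_metrics(g["obs_temp"], g["model_temp"])
        rows.append(
            {
                group: gval,
                "depth_level": level,
                "n_pairs": len(g),
                "mean_obs": float(g["obs_temp"].mean()),
                "mean_model": float(g["model_temp"].mean()),
                "bias": b,
                "urmse": urmse,
            }
        )
    return pd.DataFrame(rows).sort_values([group, "depth_level"]).reset_index(drop=True)


def plot_metric_heatmap(summary: pd.DataFrame, metric: str = "urmse", row: str = "season", col: str = "depth_range"):
    """Season × depth-range heatmap of a summary metric; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = summary.pivot(index=row, columns=col, values=metric)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(pivot.values, aspect="auto", cmap="YlOrRd")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_xlabel(col)
    ax.set_ylabel(row)
    fig.colorbar(im, ax=ax, label=f"{metric} (°C)")
    fig.tight_layout()
    return fig
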