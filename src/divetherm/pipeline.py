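"""End-to-end orchestration: simulate → decode → matchup → stats → argo-check.

All stage outputs are plain CSV (plus one netCDF field and a JSON manifest);
reruns with the same configuration are bit-identical because every random
draw derives from the run seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import argo as argo_mod
from . import decoder, matchup, stats, synthetic
from .config import RunConfig
from .params import date_range
from .regions import RegionSet

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages into ``out_dir``; returns the manifest dict.

    Outputs: ``tags/*.csv``, ``model_field.nc``, ``argo_profiles.csv``,
    ``profiles.csv``, ``rejections.csv``, ``pairs.csv``, ``summary_full.csv``,
    ``summary_table1.csv``, ``layer_by_season.csv``, ``layer_by_subregion.csv``,
    ``argo_pairs.csv``, ``argo_bias.csv`` and ``manifest.json``.
    """
    if config.regions_file and not Path(config.regions_file).exists():
        raise FileNotFoundError(f"regions file not found: {config.regions_file}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.resolve_seeds()
    dates = date_range(cfg.start_date, cfg.end_date)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "complete": False,
    }

    def record(name: str, **counts):
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    try:
        stage = "simulate"
        field = synthetic.generate_model_field(cfg.ocean, cfg.product, dates, cfg.bbox)
        field.to_netcdf(out / "model_field.nc")
        dives = synthetic.simulate_turtle_dives(cfg.turtles, cfg.ocean, dates, cfg.bbox, domain=cfg.bbox)
        tag_paths = synthetic.write_tag_files(dives, out / "tags")
        argo_df = synthetic.simulate_argo_profiles(cfg.argo, cfg.ocean, dates, cfg.bbox)
        argo_df.to_csv(out / "argo_profiles.csv", index=False)
        if cfg.regions_file:
            regions = RegionSet.from_geojson(cfg.regions_file)
        else:
            regions = RegionSet.default()
        regions.to_geojson(out / "regions.geojson")
        record(stage, n_dives=len(dives), n_tag_files=len(tag_paths), n_argo_rows=len(argo_df))

        stage = "decode"
        dec = decoder.decode_directory(out / "tags", allowed_lq=set(cfg.analysis.allowed_lq), truncate=cfg.analysis.truncate)
        prof_df = decoder.profiles_to_frame(dec.profiles)
        prof_df.to_csv(out / "profiles.csv", index=False)
        pd.DataFrame([r.__dict__ for r in dec.rejections]).to_csv(out / "rejections.csv", index=False)
        record(stage, **{k: v for k, v in dec.counts.items() if k != "files"})

        stage = "matchup"
        pairs = matchup.collocate(
            dec.profiles,
            field,
            regions,
            max_dist_km=cfg.analysis.max_match_km,
            single_sample_tol_m=cfg.analysis.single_sample_tol_m,
        )
        pairs.to_csv(out / "pairs.csv", index=False)
        record(stage, n_pairs=len(pairs), n_pairs_le_100m=int(pairs["depth_range"].notna().sum()))

        stage = "stats"
        summary = stats.stratified_summary(pairs, by=cfg.analysis.strata)
        summary.to_csv(out / "summary_full.csv", index=False)
        filtered = stats.table1_filter(summary)
        filtered.to_csv(out / "summary_table1.csv", index=False)
        for group in ("season", "subregion"):
            layer = stats.layer_profile_summary(pairs, group)
            layer.to_csv(out / f"layer_by_{group}.csv", index=False)
        record(stage, n_strata=len(summary), n_strata_reported=len(filtered))

        stage = "argo_check"
        pairings = argo_mod.pair_argo_turtle(
            prof_df, argo_df,
            max_dist_km=cfg.analysis.argo_max_dist_km,
            max_days=cfg.analysis.argo_max_days,
        )
        pairings.to_csv(out / "argo_pairs.csv", index=False)
        bins = argo_mod.binned_bias(pairings, dz=cfg.analysis.argo_dz_m, zmax=cfg.analysis.argo_zmax_m)
        bins.to_csv(out / "argo_bias.csv", index=False)
        record(stage, n_pairings=len(pairings), n_bins_occupied=int((bins["n"] > 0).sum()))
    except Exception as exc:  # noqa: BLE001 - stage-named failure contract
        manifest["failed_stage"] = stage
        _write_manifest(out, manifest)
        raise PipelineError(stage, exc) from exc

    manifest["complete"] = True
    manifest["outputs"] = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
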