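"""End-to-end orchestration: synthesize → invert → composite → validate →
fit → predict → risk → LISA.

One flat config drives every stage; a single master seed fans out
deterministically to per-stage seeds, so a rerun with the same config is
bit-identical. Every intermediate artifact is written (GeoTIFF grids, CSV
tables, JSON models) and a machine-readable run report collects per-stage
record counts and diagnostics.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from . import regression, risk as risk_mod, spatial, validation
from .atmosphere import DEFAULT_AXES, AtmosphericFunctions, ViewGeometry, build_lookup_table
from .grid import AODField, GridSpec, write_grid
from .inversion import composite_temporal, detect_clouds, invert_aod
from .seasons import MONTHS_OF_SEASON, SEASONS
from .synthetic import (
    generate_aod_field, generate_cloud_mask, generate_pm25_truth,
    generate_population, generate_station_network, sample_observations,
    synthesize_scene,
)

#: default per-season generating laws and AOD base levels (winter-high /
#: summer-low seasonal cycle); coefficients are the seasonal best fits the
#: pipeline is designed to recover
DEFAULT_SEASON_PARAMS = {
    "spring": {"family": "power", "a0": 57.754, "a1": 0.6976, "aod_base": 0.55},
    "summer": {"family": "exponential", "a0": 13.855, "a1": 0.8954, "aod_base": 0.35},
    "autumn": {"family": "power", "a0": 63.391, "a1": 0.5718, "aod_base": 0.50},
    "winter": {"family": "power", "a0": 78.184, "a1": 0.4069, "aod_base": 0.65},
}


@dataclass
class PipelineConfig:
    """Flat configuration resolving every stage's parameters."""

    n_rows: int = 40
    n_cols: int = 40
    seed: int = 7
    dates_per_season: int = 12
    noise_cv: float = 0.05
    lut_axes: dict | None = None          # None = default node set
    solar_zenith: float = 33.0
    satellite_zenith: float = 21.0
    relative_azimuth: float = 50.0
    surface_swir_mean: float = 0.12
    surface_swir_std: float = 0.04
    cloud_fraction: float = 0.08
    season_params: dict = field(default_factory=lambda: {
        s: dict(p) for s, p in DEFAULT_SEASON_PARAMS.items()})
    n_aod_stations: int = 2
    n_pm25_stations: int = 41
    station_clustering: float = 0.7
    pop_centers: int = 5
    pop_peak_density: float = 8000.0
    pop_decay_km: float = 6.0
    dark_limit: float = 0.25
    cloud_brightness: float = 0.4
    normalize_x: bool = False
    build_fraction: float = 0.7
    outlier_rule: str | None = "resid3"
    weights_scheme: str = "queen"
    alpha: float = 0.05
    n_perm: int = 199

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a config mapping; unknown keys are rejected and the
        ``lut`` block is mandatory (use ``lut: default`` for the standard
        node set)."""
        d = dict(d)
        if "lut" not in d:
            raise ValueError("config missing the required 'lut' block")
        lut = d.pop("lut")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if lut not in (None, "default"):
            cfg.lut_axes = dict(lut)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lut"] = d.pop("lut_axes") or "default"
        return d


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Prior outputs remain."""


def _season_dates(season: str, n: int) -> list[_dt.date]:
    months = MONTHS_OF_SEASON[season]
    dates = []
    for i in range(n):
        month = months[i % len(months)]
        day = 3 + 5 * (i // len(months))
        dates.append(_dt.date(2016, month, min(day, 28)))
    return sorted(dates)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(config.as_dict()), "stages": {}}
    stage = "setup"
    try:
        spec = GridSpec(config.n_rows, config.n_cols)
        geom = ViewGeometry(config.solar_zenith, config.satellite_zenith,
                            config.relative_azimuth)
        seeds = np.random.SeedSequence(config.seed).spawn(8)
        atm = AtmosphericFunctions()
        lut = build_lookup_table(atm, config.lut_axes)
        lut.save(out / "lut.npz")

        stage = "synthesize"
        rng_pop = np.random.default_rng(seeds[0])
        population = generate_population(
            spec, config.pop_centers, config.pop_peak_density,
            config.pop_decay_km, seed=int(rng_pop.integers(2 ** 31)))
        network = generate_station_network(
            spec, config.n_aod_stations, config.n_pm25_stations,
            config.station_clustering, seed=int(rng_pop.integers(2 ** 31)),
            population=population)
        write_grid(out / "population.tif", population.density, spec)
        network.stations.to_csv(out / "stations.csv", index=False)

        surf_rng = np.random.default_rng(seeds[1])
        surface = np.clip(
            config.surface_swir_mean
            + config.surface_swir_std * gaussian_filter(
                surf_rng.standard_normal(spec.shape), 3, mode="reflect") * 6.0,
            0.02, 0.24)

        day_rng = np.random.default_rng(seeds[2])
        truth_aod: dict[str, dict] = {s: {} for s in SEASONS}
        truth_pm: dict[str, dict] = {s: {} for s in SEASONS}
        scenes: dict[str, dict] = {s: {} for s in SEASONS}
        n_scenes = 0
        for season in SEASONS:
            params = config.season_params[season]
            for date in _season_dates(season, config.dates_per_season):
                iso = date.isoformat()
                s1, s2, s3 = (int(day_rng.integers(2 ** 31)) for _ in range(3))
                base = float(np.clip(
                    params["aod_base"] + day_rng.normal(0, 0.15), 0.10, 1.20))
                aod = generate_aod_field(
                    spec, smoothness=6.0, gradient=(90.0, 0.3),
                    value_range=(0.02, 1.90), seed=s1, base=base,
                    noise_scale=0.12)
                pm = generate_pm25_truth(
                    aod, params["family"], params["a0"], params["a1"],
                    noise_cv=config.noise_cv, seed=s2)
                clouds = generate_cloud_mask(spec, config.cloud_fraction, seed=s3)
                scenes[season][iso] = synthesize_scene(
                    aod, surface, geom, atm, date=iso, cloud_mask=clouds)
                truth_aod[season][iso] = aod
                truth_pm[season][iso] = pm
                n_scenes += 1
        report["stages"]["synthesize"] = {
            "n_scenes": n_scenes, "n_stations": len(network),
            "population_total": float(population.density.sum()),
        }

        stage = "invert"
        daily_aod: dict[str, dict] = {s: {} for s in SEASONS}
        valid_frac = {}
        for season in SEASONS:
            fracs = []
            for iso, scene in scenes[season].items():
                scene.cloud_mask = detect_clouds(
                    scene, brightness_threshold=config.cloud_brightness)
                fieldd = invert_aod(scene, lut, dark_limit=config.dark_limit)
                daily_aod[season][iso] = fieldd
                fracs.append(float(np.isfinite(fieldd.tau550).mean()))
            valid_frac[season] = float(np.mean(fracs))
        report["stages"]["invert"] = {"mean_valid_fraction": valid_frac}

        stage = "composite"
        seasonal_aod: dict[str, AODField] = {}
        seasonal_truth_aod: dict[str, AODField] = {}
        for season in SEASONS:
            monthly, monthly_truth = [], []
            for month in MONTHS_OF_SEASON[season]:
                keys = [k for k in daily_aod[season] if int(k[5:7]) == month]
                if not keys:
                    continue
                monthly.append(composite_temporal(
                    [daily_aod[season][k] for k in keys], f"2016-{month:02d}"))
                monthly_truth.append(composite_temporal(
                    [truth_aod[season][k] for k in keys], f"2016-{month:02d}"))
            seasonal_aod[season] = composite_temporal(monthly, season)
            seasonal_truth_aod[season] = composite_temporal(monthly_truth, season)
            write_grid(out / f"aod_{season}.tif", seasonal_aod[season].tau550, spec)
        report["stages"]["composite"] = {
            s: {"valid_cells": int(np.isfinite(f.tau550).sum())}
            for s, f in seasonal_aod.items()}

        stage = "validate"
        obs_rng = np.random.default_rng(seeds[3])
        aod_records = []
        aod_net = network.of_kind("AOD")
        channels = np.array([440.0, 500.0, 675.0, 870.0])
        for season in SEASONS:
            for iso, aod in truth_aod[season].items():
                for _, st in aod_net.iterrows():
                    tau550 = aod.tau550[int(st["row"]), int(st["col"])]
                    if not np.isfinite(tau550) or tau550 <= 0:
                        continue
                    alpha_st = 1.3
                    beta = tau550 * 0.55 ** alpha_st
                    tau_ch = beta * (channels / 1000.0) ** (-alpha_st)
                    tau_ch = tau_ch * np.exp(obs_rng.normal(0, 0.015, len(channels)))
                    aod_records.append((st["station_id"], iso,
                                        validation.spectral_to_550(channels, tau_ch)))
        ground_aod = pd.DataFrame(aod_records, columns=["station_id", "date", "value"])
        all_daily = {k: v for s in SEASONS for k, v in daily_aod[s].items()}
        aod_pairs = validation.collocate(all_daily, network, ground_aod, kind="AOD")
        aod_pairs.to_csv(out / "aod_collocation.csv", index=False)
        if len(aod_pairs) >= 3:
            vrep = validation.validate_pairs(aod_pairs)
            report["stages"]["validate"] = {"n_pairs": len(aod_pairs), **vrep.as_dict()}
        else:
            report["stages"]["validate"] = {"n_pairs": len(aod_pairs)}

        stage = "collocate"
        pm_obs_rng = np.random.default_rng(seeds[4])
        frames = []
        for season in SEASONS:
            obs = sample_observations(
                truth_pm[season], network,
                dates=sorted(truth_pm[season]), obs_noise_cv=0.0,
                missing_rate=0.0, seed=int(pm_obs_rng.integers(2 ** 31)),
                kind="PM25")
            pairs = validation.collocate(daily_aod[season], network, obs, kind="PM25")
            frames.append(pairs)
        pm_pairs = pd.concat(frames, ignore_index=True)
        pm_pairs = pm_pairs[pm_pairs["x"] > 0].reset_index(drop=True)
        pm_pairs.to_csv(out / "pm25_pairs.csv", index=False)
        report["stages"]["collocate"] = {
            "n_pairs": {s: int((pm_pairs["season"] == s).sum()) for s in SEASONS}}

        stage = "fit"
        splits = regression.split_by_season(
            pm_pairs, build_fraction=config.build_fraction,
            outlier_rule=config.outlier_rule)
        models = {}
        fit_report = {}
        for season in SEASONS:
            sp = splits[season]
            candidates = regression.fit_all_families(
                sp.build["x"].to_numpy(), sp.build["y"].to_numpy(),
                season=season, normalize_x=config.normalize_x)
            best = regression.select_model(
                candidates, sp.verify["x"].to_numpy(), sp.verify["y"].to_numpy())
            models[season] = best
            (out / f"model_{season}.json").write_text(best.to_json())
            fit_report[season] = {
                "family": best.family,
                "coefficients": list(best.coefficients),
                "n_build": len(sp.build), "n_verify": len(sp.verify),
                "n_eliminated": len(sp.eliminated),
                "r2_build": best.diagnostics.get("r2_build"),
                "r2_verify": best.diagnostics.get("r2_verify"),
                "rmse_verify": best.diagnostics.get("rmse_verify"),
            }
        report["stages"]["fit"] = fit_report

        stage = "predict"
        pm_grids = {}
        predict_report = {}
        for season in SEASONS:
            pred = regression.predict_grid(models[season], seasonal_aod[season].tau550)
            pm_grids[season] = pred
            write_grid(out / f"pm25_{season}.tif", pred, spec)
            params = config.season_params[season]
            truth_grid = generate_pm25_truth(
                seasonal_truth_aod[season], params["family"], params["a0"],
                params["a1"], noise_cv=0.0)
            both = np.isfinite(pred) & np.isfinite(truth_grid) & (truth_grid > 0)
            rel = np.abs(pred[both] - truth_grid[both]) / truth_grid[both]
            predict_report[season] = {
                "valid_cells": int(both.sum()),
                "median_rel_error": float(np.median(rel)) if both.any() else None,
            }
        stack = np.stack([pm_grids[s] for s in SEASONS])
        finite = np.isfinite(stack)
        annual = np.where(finite.any(0), np.where(finite, stack, 0).sum(0)
                          / np.maximum(finite.sum(0), 1), np.nan)
        write_grid(out / "pm25_annual.tif", annual, spec)
        report["stages"]["predict"] = predict_report

        stage = "risk"
        rgrid = risk_mod.relative_risk(annual, population)
        write_grid(out / "risk_q.tif", rgrid.q, spec)
        write_grid(out / "risk_level.tif",
                   np.where(rgrid.level >= 0, rgrid.level.astype(float), np.nan), spec)
        half_r, half_c = spec.n_rows // 2, spec.n_cols // 2
        regions = (np.add.outer((np.arange(spec.n_rows) >= half_r).astype(int) * 2,
                                (np.arange(spec.n_cols) >= half_c).astype(int)))
        by_region = risk_mod.aggregate_regions(rgrid, regions)
        by_region.to_csv(out / "risk_by_region.csv", index=False)
        level_counts = {risk_mod.RISK_LEVELS[i]: int((rgrid.level == i).sum())
                        for i in range(6)}
        report["stages"]["risk"] = {
            "mean_q": float(np.nanmean(rgrid.q)),
            "max_q": float(np.nanmax(rgrid.q)),
            "level_counts": level_counts,
            "by_region": by_region.to_dict("records"),
        }

        stage = "lisa"
        res = spatial.lisa(rgrid.q, scheme=config.weights_scheme,
                           alpha=config.alpha, n_perm=config.n_perm,
                           seed=int(np.random.default_rng(seeds[5]).integers(2 ** 31)))
        write_grid(out / "lisa_local_i.tif", res.local_i, spec)
        write_grid(out / "lisa_p.tif", res.p, spec)
        write_grid(out / "lisa_cluster.tif", res.cluster.astype(float), spec)
        cluster_counts = {name: int((res.cluster == code).sum())
                          for code, name in spatial.CLUSTER_NAMES.items()}
        report["stages"]["lisa"] = {
            "global_i": float(res.global_i), "cluster_counts": cluster_counts}
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
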