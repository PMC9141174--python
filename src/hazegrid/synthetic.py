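"""Synthetic scene, station, and population generators with known ground truth.

Every pipeline stage gets a parameter-recovery surface: spatially
autocorrelated AOD fields with a coastal-high/inland-low gradient, PM2.5
fields generated from the seasonal regression families, clustered monitoring
networks, multi-center population surfaces, cloud masks, and full multiband
reflectance scenes produced by the shared forward model. All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .atmosphere import AtmosphericFunctions, ViewGeometry, toa_reflectance
from .grid import AODField, GridSpec
from .inversion import BAND_BLUE, BAND_RED, BAND_SWIR, ReflectanceScene, estimate_surface_reflectance
from .regression import FAMILIES, evaluate_family

AOD_RANGE = (0.0, 1.95)


@dataclass
class StationNetwork:
    """Monitoring sites at grid cells; kind is "AOD" or "PM25"."""

    stations: pd.DataFrame  # columns: station_id, row, col, kind

    def __post_init__(self) -> None:
        required = {"station_id", "row", "col", "kind"}
        if not required.issubset(self.stations.columns):
            raise ValueError(f"stations table needs columns {sorted(required)}")
        if self.stations["station_id"].duplicated().any():
            raise ValueError("station ids must be unique")

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.stations[self.stations["kind"] == kind].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.stations)


@dataclass
class PopulationGrid:
    density: np.ndarray  # persons per km² per cell
    spec: GridSpec

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != self.spec.shape:
            raise ValueError("density shape does not match grid spec")
        if np.any(self.density < 0):
            raise ValueError("population density must be non-negative")
        if not np.any(self.density > 0):
            raise ValueError("population grid must contain at least one inhabited cell")


@dataclass
class TruthBundle:
    """Ground truth for one season: AOD field, PM2.5 field, generating law."""

    aod_field: AODField
    pm25_field: np.ndarray
    season_params: dict
    cloud_mask: np.ndarray
    seed: int


def _lognormal_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv < 0:
        raise ValueError("noise coefficient of variation must be >= 0")
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv ** 2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), shape))


def generate_aod_field(spec: GridSpec, smoothness: float = 6.0,
                       gradient: tuple[float, float] = (90.0, 0.3),
                       value_range: tuple[float, float] = AOD_RANGE,
                       seed: int = 0, base: float = 0.5,
                       noise_scale: float = 0.15) -> AODField:
    """Spatially autocorrelated AOD field, clipped to ``value_range``.

    Structure = base level + linear gradient + Gaussian-smoothed white noise.
    ``smoothness`` is the smoothing length scale in cells; ``gradient`` is
    (direction in degrees clockwise from north toward which values increase,
    amplitude across the grid). The default eastward gradient emulates a
    coastal-high / inland-low pattern.
    """
    lo, hi = value_range
    if not (AOD_RANGE[0] <= lo < hi <= AOD_RANGE[1]):
        raise ValueError(
            f"value_range must be a sub-interval of [{AOD_RANGE[0]}, {AOD_RANGE[1]}]")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive (cells)")
    rng = np.random.default_rng(seed)
    direction, amplitude = gradient
    field = np.full(spec.shape, float(base))
    if amplitude != 0:
        rows, cols = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
        u_north = 0.5 - rows / max(spec.n_rows - 1, 1)       # +0.5 at top edge
        u_east = cols / max(spec.n_cols - 1, 1) - 0.5        # +0.5 at right edge
        rad = np.radians(direction)
        field = field + amplitude * (np.cos(rad) * u_north + np.sin(rad) * u_east)
    if noise_scale != 0:
        white = rng.standard_normal(spec.shape)
        smooth = gaussian_filter(white, sigma=smoothness, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            field = field + noise_scale * smooth / sd
    return AODField(np.clip(field, lo, hi), spec)


def generate_pm25_truth(aod: AODField | np.ndarray, family: str, a0: float, a1: float,
                        noise_cv: float = 0.0, seed: int = 0,
                        a2: float = 0.0, a3: float = 0.0) -> np.ndarray:
    """PM2.5 grid from an AOD grid under one regression family.

    y = family(a0, a1[, a2, a3])(AOD) × mean-one lognormal noise; results are
    floored at 0 and nodata propagates.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; known: {sorted(FAMILIES)}")
    values = aod.tau550 if isinstance(aod, AODField) else np.asarray(aod, dtype=float)
    coeffs = (a0, a1, a2, a3)[: FAMILIES[family]]
    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore"):
        y = evaluate_family(family, coeffs, values)
    y = y * _lognormal_factor(rng, noise_cv, values.shape)
    y = np.where(np.isfinite(y), np.maximum(y, 0.0), np.nan)
    return y


def generate_population(spec: GridSpec, n_centers: int = 5,
                        peak_density: float = 8000.0, decay: float = 6.0,
                        seed: int = 0) -> PopulationGrid:
    """Multi-center population surface: sum of exponential kernels.

    Each center contributes ``peak_density × exp(−d/decay)`` with d the
    Euclidean cell distance; ``decay`` is in cells (= km on the 1-km grid).
    """
    if n_centers < 1:
        raise ValueError("need at least one population center")
    if peak_density <= 0:
        raise ValueError("peak_density must be positive")
    if decay <= 0:
        raise ValueError("decay length must be positive")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
    density = np.zeros(spec.shape)
    centers = np.column_stack([
        rng.integers(0, spec.n_rows, n_centers),
        rng.integers(0, spec.n_cols, n_centers),
    ])
    for r0, c0 in centers:
        d = np.hypot(rows - r0, cols - c0)
        with np.errstate(under="ignore"):
            density += peak_density * np.exp(-d / decay)
    return PopulationGrid(density, spec)


def generate_station_network(spec: GridSpec, n_aod: int = 2, n_pm25: int = 41,
                             clustering: float = 0.7, seed: int = 0,
                             population: PopulationGrid | None = None) -> StationNetwork:
    """Place AOD and PM2.5 stations on unique cells.

    With ``clustering`` > 0 and a population surface, placement probability
    mixes a uniform component with one proportional to the (lightly smoothed)
    population density, emulating networks concentrated in developed areas.
    """
    if n_aod < 0 or n_pm25 < 0:
        raise ValueError("station counts must be non-negative")
    total = n_aod + n_pm25
    if total > spec.n_cells:
        raise ValueError(
            f"requested {total} stations but the grid has {spec.n_cells} cells")
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    weights = np.full(spec.n_cells, 1.0 / spec.n_cells)
    if clustering > 0 and population is not None:
        smoothed = gaussian_filter(population.density, sigma=1.0, mode="nearest")
        pop_w = smoothed.ravel()
        pop_w = pop_w / pop_w.sum()
        weights = (1.0 - clustering) * weights + clustering * pop_w
    candidates = np.flatnonzero(weights > 0)
    if total > len(candidates):
        raise ValueError("not enough cells with positive placement weight")
    chosen = rng.choice(candidates, size=total, replace=False,
                        p=weights[candidates] / weights[candidates].sum())
    rows_, cols_ = np.unravel_index(chosen, spec.shape)
    kinds = ["AOD"] * n_aod + ["PM25"] * n_pm25
    ids = [f"{k.lower()}_{i:03d}" for i, k in enumerate(kinds)]
    return StationNetwork(pd.DataFrame(
        {"station_id": ids, "row": rows_, "col": cols_, "kind": kinds}))


def sample_observations(field, network: StationNetwork, dates,
                        obs_noise_cv: float = 0.0, missing_rate: float = 0.0,
                        seed: int = 0, kind: str | None = None) -> pd.DataFrame:
    """Station observation table from gridded truth.

    ``field`` is a single grid (used for every date) or a mapping
    date → grid. One record per (station, date) survives Bernoulli dropout at
    ``missing_rate``; values are the field value at the station cell times
    mean-one lognormal noise. Columns: station_id, date (ISO), value.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    stations = network.of_kind(kind) if kind else network.stations
    records = []
    for date in dates:
        grid = field[date] if isinstance(field, dict) else field
        grid = grid.tau550 if isinstance(grid, AODField) else np.asarray(grid, dtype=float)
        for _, st in stations.iterrows():
            r, c = int(st["row"]), int(st["col"])
            if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
                raise ValueError(f"station {st['station_id']} outside the grid")
            value = grid[r, c] * _lognormal_factor(rng, obs_noise_cv, ())
            keep = rng.random() >= missing_rate
            if keep and np.isfinite(value):
                records.append((st["station_id"], _iso(date), float(value)))
    return pd.DataFrame(records, columns=["station_id", "date", "value"])


def _iso(date) -> str:
    if isinstance(date, (_dt.date, _dt.datetime)):
        return date.strftime("%Y-%m-%d")
    return str(date)


def generate_cloud_mask(spec: GridSpec, cloud_fraction: float = 0.1,
                        blob_radius: float = 3.0, seed: int = 0) -> np.ndarray:
    """Bright-blob cloud mask covering approximately ``cloud_fraction`` of cells."""
    if not 0.0 <= cloud_fraction < 1.0:
        raise ValueError("cloud_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = np.zeros(spec.shape, dtype=bool)
    if cloud_fraction == 0:
        return mask
    rows, cols = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
    target = cloud_fraction * spec.n_cells
    guard = 0
    while mask.sum() < target and guard < 10 * spec.n_cells:
        r0 = rng.integers(0, spec.n_rows)
        c0 = rng.integers(0, spec.n_cols)
        mask |= np.hypot(rows - r0, cols - c0) <= blob_radius
        guard += 1
    return mask


def synthesize_scene(aod: AODField, surface_swir: np.ndarray, geom: ViewGeometry,
                     atm: AtmosphericFunctions, date="",
                     cloud_mask: np.ndarray | None = None,
                     cloud_reflectance: float = 0.75) -> ReflectanceScene:
    """Forward-model a reflectance scene from true AOD and 2.1-µm surface.

    Visible surface reflectances follow the dark-target ratios so the
    retrieval assumption is exact in the synthetic world. Cloudy cells are
    overwritten with a uniformly bright reflectance in all bands.
    """
    surface_swir = np.asarray(surface_swir, dtype=float)
    surf_r, surf_b = estimate_surface_reflectance(surface_swir)
    tau = aod.tau550
    bands = {}
    for band, surf in ((BAND_BLUE, surf_b), (BAND_RED, surf_r), (BAND_SWIR, surface_swir)):
        ok = np.isfinite(surf) & np.isfinite(tau)
        out = np.full(aod.spec.shape, np.nan)
        out[ok] = toa_reflectance(surf[ok], tau[ok], geom, band, atm)
        if cloud_mask is not None:
            out[cloud_mask] = cloud_reflectance
        bands[band] = out
    return ReflectanceScene(bands, geom, aod.spec, date=date, cloud_mask=None)
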