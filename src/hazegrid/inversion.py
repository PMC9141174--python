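"""Dark-target AOD retrieval from multiband apparent reflectance scenes.

The dark-target principle: over dark (vegetated) surfaces the 2.1-µm band is
essentially unaffected by aerosol, so its apparent reflectance estimates the
surface reflectance; visible-band surface reflectances follow from the fixed
ratios ρ_red = ρ_2.1/2 and ρ_blue = ρ_2.1/4. Given the surface, the aerosol
optical depth is the value whose forward-modelled apparent reflectance (from
the lookup table) matches the observed visible-band reflectance; the forward
curve is strictly increasing in τ over dark surfaces, so the match is unique.

Because the LUT is interpolated multilinearly, the forward curve at fixed
geometry is piecewise linear in τ and every cell's τ is solved exactly per
segment, vectorised over the scene.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .atmosphere import LookupTable, ViewGeometry, atm_node_curves
from .grid import AODField, GridSpec

BAND_SWIR = 2100
BAND_RED = 660
BAND_BLUE = 470

#: conventional dark-pixel admissibility threshold on 2.1-µm reflectance
DEFAULT_DARK_LIMIT = 0.25


@dataclass
class ReflectanceScene:
    """One acquisition: apparent reflectance at 0.47/0.66/2.1 µm + geometry."""

    bands: dict[int, np.ndarray]
    geometry: ViewGeometry
    spec: GridSpec
    date: _dt.date | str = ""
    cloud_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for b in (BAND_BLUE, BAND_RED, BAND_SWIR):
            if b not in self.bands:
                raise ValueError(f"scene missing band {b}")
            arr = np.asarray(self.bands[b], dtype=float)
            if arr.shape != self.spec.shape:
                raise ValueError("all bands must share the scene grid")
            vals = arr[np.isfinite(arr)]
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError("reflectances must lie in [0, 1] or be nodata")
            self.bands[b] = arr
        if self.cloud_mask is not None:
            self.cloud_mask = np.asarray(self.cloud_mask, dtype=bool)
            if self.cloud_mask.shape != self.spec.shape:
                raise ValueError("cloud mask must share the scene grid")


def estimate_surface_reflectance(rho_n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Visible surface reflectance from the 2.1-µm band: (ρn/2, ρn/4).

    Nodata (NaN) propagates to both outputs.
    """
    rho_n = np.asarray(rho_n, dtype=float)
    vals = rho_n[np.isfinite(rho_n)]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("2.1 um reflectance must lie in [0, 1] or be nodata")
    return rho_n / 2.0, rho_n / 4.0


def detect_clouds(scene: ReflectanceScene, brightness_threshold: float = 0.4,
                  uniformity_window: int = 3, uniformity_limit: float = 0.08) -> np.ndarray:
    """Proxy cloud screen: bright-in-blue OR locally non-uniform cells.

    A cell is flagged when its blue apparent reflectance exceeds the
    brightness threshold, or the standard deviation in the surrounding
    window exceeds ``uniformity_limit``. This is a stand-in for an
    operational cloud product and is labelled as such.
    """
    if not 0 < brightness_threshold < 1:
        raise ValueError("brightness_threshold must lie in (0, 1)")
    if uniformity_window < 1:
        raise ValueError("uniformity window must be at least 1 cell")
    blue = np.asarray(scene.bands[BAND_BLUE], dtype=float)
    filled = np.where(np.isfinite(blue), blue, 0.0)
    mean = uniform_filter(filled, size=uniformity_window, mode="nearest")
    sq = uniform_filter(filled ** 2, size=uniformity_window, mode="nearest")
    local_sd = np.sqrt(np.maximum(sq - mean ** 2, 0.0))
    mask = (filled > brightness_threshold) | (local_sd > uniformity_limit)
    mask &= np.isfinite(blue)
    return mask


def _invert_band(obs: np.ndarray, surface: np.ndarray, lut: LookupTable,
                 geom: ViewGeometry, band: int) -> np.ndarray:
    """Exact piecewise-linear τ solve for one band; NaN where not bracketed low.

    Observations above the τ=1.95 node are clipped to 1.95 (the stated
    retrieval range); observations below the clean-atmosphere node (i.e.
    darker than the estimated surface) are unretrievable.
    """
    tau_axis, rho_a, trans, sph = atm_node_curves(lut, geom, band)
    # node-level forward curves per cell: shape (n_tau, n_cells)
    surf = surface[None, :]
    curves = rho_a[:, None] + trans[:, None] * surf / (1.0 - surf * sph[:, None])
    seg = (curves <= obs[None, :]).sum(axis=0) - 1  # index of left node
    tau = np.full(obs.shape, np.nan)
    below = seg < 0
    above = seg >= len(tau_axis) - 1
    tau[above] = tau_axis[-1]
    mid = ~(below | above)
    idx = seg[mid]
    c0 = curves[idx, np.flatnonzero(mid)]
    c1 = curves[idx + 1, np.flatnonzero(mid)]
    denom = c1 - c0
    frac = np.where(denom > 0, (obs[mid] - c0) / np.where(denom > 0, denom, 1.0), 0.0)
    tau[mid] = tau_axis[idx] + frac * (tau_axis[idx + 1] - tau_axis[idx])
    return tau


def invert_aod(scene: ReflectanceScene, lut: LookupTable,
               dark_limit: float = DEFAULT_DARK_LIMIT) -> AODField:
    """Retrieve τ550 per cell; red and blue retrievals are averaged.

    Cells are nodata when cloud-masked, brighter than the dark-pixel limit at
    2.1 µm, missing any band, or unbracketed in both visible bands. Retrieved
    values are clipped to [0, 1.95].
    """
    if not 0 < dark_limit < 1:
        raise ValueError("dark_limit must lie in (0, 1)")
    for b in (BAND_BLUE, BAND_RED):
        lut.band_index(b)
    rho_n = scene.bands[BAND_SWIR]
    valid = np.isfinite(rho_n)
    for b in (BAND_BLUE, BAND_RED):
        valid &= np.isfinite(scene.bands[b])
    if scene.cloud_mask is not None:
        valid &= ~scene.cloud_mask
    valid &= ~(rho_n > dark_limit)

    tau = np.full(scene.spec.shape, np.nan)
    if valid.any():
        surf_r, surf_b = estimate_surface_reflectance(rho_n[valid])
        tau_r = _invert_band(scene.bands[BAND_RED][valid], surf_r, lut,
                             scene.geometry, BAND_RED)
        tau_b = _invert_band(scene.bands[BAND_BLUE][valid], surf_b, lut,
                             scene.geometry, BAND_BLUE)
        both = np.stack([tau_r, tau_b])
        finite = np.isfinite(both)
        count = finite.sum(axis=0)
        total = np.where(finite, both, 0.0).sum(axis=0)
        merged = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        tau[valid] = np.clip(merged, 0.0, 1.95)
    return AODField(tau, scene.spec, period=str(scene.date))


def composite_temporal(daily: list[AODField], period: str) -> AODField:
    """Cellwise mean over the fields in which the cell is valid.

    A cell is valid in the composite iff it is valid in at least one input:
    cloud-blocked days simply do not participate at that cell. Seasonal
    composites should be built from monthly composites (mean of monthly
    means), not by pooling days — coverage is rarely even across months.
    """
    if not daily:
        raise ValueError("cannot composite an empty field list")
    spec = daily[0].spec
    for f in daily:
        if f.spec != spec:
            raise ValueError("all fields must share one grid spec")
    stack = np.stack([f.tau550 for f in daily])
    finite = np.isfinite(stack)
    count = finite.sum(axis=0)
    total = np.where(finite, stack, 0.0).sum(axis=0)
    out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return AODField(out, spec, period=period)
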