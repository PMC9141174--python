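"""Parametric atmospheric forward model and lookup table (LUT).

The aerosol retrieval needs three atmospheric quantities as functions of the
550-nm aerosol optical depth τ and the viewing geometry: the path reflectance
ρa, the two-way transmittance product T = T(μ0)·T(μ), and the atmospheric
spherical albedo s. A full radiative-transfer code would tabulate these; here
they come from a documented single-scattering-style parametric family with the
same interface, so an externally computed table can be dropped in unchanged.

The family is

    ρa(τ, g, λ) = A(g, λ) · (1 − T(τ, g, λ)),   A = C·P(Θ)/(μ + μ0)
    T(τ, g, λ)  = exp(−b · τλ · (1/μ + 1/μ0) / 2)
    s(τ, λ)     = c · (1 − exp(−τλ))

with τλ = τ550·(λ/550 nm)^−α the band optical depth under an Angstrom
wavelength scaling, and P(Θ) = 3/4·(1 + cos²Θ) a Rayleigh-type phase function
of the scattering angle Θ. The 2.1-µm band is treated as aerosol-transparent
(τλ ≡ 0): at that wavelength fine-mode aerosol extinction is negligible, and
the dark-target surface-reflectance identity then holds exactly.

Sharing the exponential T between ρa and the transmittance makes the
top-of-atmosphere reflectance provably strictly increasing in τ for any
surface darker than A/(1+s) — the whole dark-target admissible range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

TAU_MAX = 1.95

#: default central wavelengths (nm): blue, red, 2.1 µm
DEFAULT_BANDS = (470, 660, 2100)


@dataclass(frozen=True)
class ViewGeometry:
    """Sun-satellite geometry, degrees. Zeniths span the LUT range [0°, 60°]."""

    solar_zenith: float
    satellite_zenith: float
    relative_azimuth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.solar_zenith <= 60.0:
            raise ValueError("solar_zenith must be in [0, 60] degrees")
        if not 0.0 <= self.satellite_zenith <= 60.0:
            raise ValueError("satellite_zenith must be in [0, 60] degrees")
        if not 0.0 <= self.relative_azimuth <= 180.0:
            raise ValueError("relative_azimuth must be in [0, 180] degrees")

    @property
    def mu0(self) -> float:
        return float(np.cos(np.radians(self.solar_zenith)))

    @property
    def mu(self) -> float:
        return float(np.cos(np.radians(self.satellite_zenith)))

    def scattering_cosine(self) -> float:
        """cos Θ of the scattering angle (forward scattering → +1)."""
        s0 = np.sin(np.radians(self.solar_zenith))
        s1 = np.sin(np.radians(self.satellite_zenith))
        return float(
            -self.mu * self.mu0
            + s0 * s1 * np.cos(np.radians(self.relative_azimuth))
        )


@dataclass(frozen=True)
class AtmosphericFunctions:
    """The parametric (ρa, T, s) family; see module docstring for the formulas."""

    path_amplitude: float = 0.4     # C: scales the saturated path reflectance
    extinction_coeff: float = 0.4   # b: transmittance decay per unit slant τ
    spherical_albedo_max: float = 0.25  # c: limiting spherical albedo, < 1
    angstrom_exponent: float = 1.8  # α: spectral scaling of τ between bands
    bands: tuple[int, ...] = DEFAULT_BANDS
    transparent_bands: tuple[int, ...] = (2100,)

    def band_tau(self, tau550, band: int):
        """Band optical depth τλ from τ550 (zero for transparent bands)."""
        if band not in self.bands:
            raise KeyError(f"unknown band {band}; have {self.bands}")
        tau550 = np.asarray(tau550, dtype=float)
        if band in self.transparent_bands:
            return np.zeros_like(tau550)
        return tau550 * (band / 550.0) ** (-self.angstrom_exponent)

    def _amplitude(self, geom: ViewGeometry) -> float:
        phase = 0.75 * (1.0 + geom.scattering_cosine() ** 2)
        return self.path_amplitude * phase / (geom.mu + geom.mu0)

    def transmittance_product(self, tau550, geom: ViewGeometry, band: int):
        taub = self.band_tau(tau550, band)
        m = 1.0 / geom.mu + 1.0 / geom.mu0  # two-way air-mass factor
        return np.exp(-self.extinction_coeff * taub * m / 2.0)

    def path_reflectance(self, tau550, geom: ViewGeometry, band: int):
        return self._amplitude(geom) * (1.0 - self.transmittance_product(tau550, geom, band))

    def spherical_albedo(self, tau550, band: int):
        return self.spherical_albedo_max * (1.0 - np.exp(-self.band_tau(tau550, band)))


def toa_reflectance(surface_refl, tau550, geom: ViewGeometry, band: int,
                    atm: AtmosphericFunctions):
    """Apparent (top-of-atmosphere) reflectance ρ* = ρa + T·ρ/(1 − ρ·s).

    ``surface_refl`` and ``tau550`` broadcast; the result is clipped to [0, 1].
    Raises if ρ·s ≥ 1 (multiple-scattering series divergence).
    """
    rho = np.asarray(surface_refl, dtype=float)
    tau = np.asarray(tau550, dtype=float)
    if np.any((rho < 0) | (rho >= 1)):
        raise ValueError("surface reflectance must lie in [0, 1)")
    if np.any((tau < 0) | (tau > TAU_MAX)):
        raise ValueError(f"tau550 must lie in [0, {TAU_MAX}]")
    rho_a = atm.path_reflectance(tau, geom, band)
    t = atm.transmittance_product(tau, geom, band)
    s = atm.spherical_albedo(tau, band)
    if np.any(rho * s >= 1.0):
        raise ValueError("rho*s >= 1: multiple-scattering divergence")
    out = rho_a + t * rho / (1.0 - rho * s)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Lookup table


#: default LUT axes: 6 zenith nodes each, azimuth 0..180 step 24 with the
#: 180° endpoint appended, 6 τ nodes, 3 bands
DEFAULT_AXES = {
    "satellite_zenith": (0.0, 12.0, 24.0, 36.0, 48.0, 60.0),
    "solar_zenith": (0.0, 12.0, 24.0, 36.0, 48.0, 60.0),
    "relative_azimuth": (0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 180.0),
    "tau550": (0.0, 0.25, 0.50, 1.00, 1.50, 1.95),
    "bands": DEFAULT_BANDS,
}

_CONT_AXES = ("satellite_zenith", "solar_zenith", "relative_azimuth", "tau550")


@dataclass
class LookupTable:
    """Tabulated (ρa, T, s) on a geometry × τ × band grid.

    ``rho_a``, ``trans``, ``sph_alb`` have shape
    (n_sat_zen, n_sol_zen, n_azimuth, n_tau, n_bands).
    """

    axes: dict
    rho_a: np.ndarray
    trans: np.ndarray
    sph_alb: np.ndarray
    _interps: dict = field(default_factory=dict, repr=False)

    def band_index(self, band: int) -> int:
        bands = tuple(self.axes["bands"])
        if band not in bands:
            raise KeyError(f"LUT missing band {band}; have {bands}")
        return bands.index(band)

    def validate(self) -> None:
        for name in _CONT_AXES:
            ax = np.asarray(self.axes[name], dtype=float)
            if ax.ndim != 1 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"axis {name!r} must be strictly increasing")
        if len(self.axes["tau550"]) < 2:
            raise ValueError("tau550 axis needs at least 2 nodes for inversion")
        # monotone-in-τ path reflectance guarantees a unique inversion root
        for bi, band in enumerate(self.axes["bands"]):
            sl = self.rho_a[..., bi]
            if band not in (2100,) and np.any(np.diff(sl, axis=-1) <= 0):
                raise ValueError(f"rho_a not strictly increasing in tau for band {band}")

    def _interp(self, name: str, table: np.ndarray):
        key = name
        if key not in self._interps:
            pts = tuple(np.asarray(self.axes[a], dtype=float) for a in _CONT_AXES)
            self._interps[key] = {
                bi: RegularGridInterpolator(pts, table[..., bi], method="linear",
                                            bounds_error=True)
                for bi in range(table.shape[-1])
            }
        return self._interps[key]

    def save(self, path) -> None:
        np.savez(
            path,
            rho_a=self.rho_a, trans=self.trans, sph_alb=self.sph_alb,
            **{f"axis_{k}": np.asarray(v, dtype=float) for k, v in self.axes.items()},
        )

    @classmethod
    def load(cls, path) -> "LookupTable":
        with np.load(path) as z:
            axes = {
                k[5:]: tuple(z[k].tolist()) for k in z.files if k.startswith("axis_")
            }
            axes["bands"] = tuple(int(b) for b in axes["bands"])
            lut = cls(axes=axes, rho_a=z["rho_a"], trans=z["trans"], sph_alb=z["sph_alb"])
        lut.validate()
        return lut


def build_lookup_table(atm: AtmosphericFunctions, axes: dict | None = None) -> LookupTable:
    """Evaluate the forward model at every LUT node.

    ``axes`` defaults to the standard node set (6 zenith nodes, 24°-step
    azimuths with the 180° endpoint, τ ∈ {0, 0.25, 0.5, 1.0, 1.5, 1.95}).
    """
    axes = dict(DEFAULT_AXES if axes is None else axes)
    for name in _CONT_AXES:
        ax = np.asarray(axes[name], dtype=float)
        if ax.ndim != 1 or len(ax) < 1 or np.any(np.diff(ax) <= 0):
            raise ValueError(f"axis {name!r} must be 1-D strictly increasing")
    if len(axes["tau550"]) < 2:
        raise ValueError("tau550 axis needs at least 2 nodes (inversion impossible with 1)")
    sat = np.asarray(axes["satellite_zenith"], float)
    sol = np.asarray(axes["solar_zenith"], float)
    az = np.asarray(axes["relative_azimuth"], float)
    tau = np.asarray(axes["tau550"], float)
    bands = tuple(axes["bands"])
    shape = (len(sat), len(sol), len(az), len(tau), len(bands))
    rho_a = np.empty(shape)
    trans = np.empty(shape)
    sph = np.empty(shape)
    for i, sz in enumerate(sat):
        for j, oz in enumerate(sol):
            for k, ra in enumerate(az):
                g = ViewGeometry(oz, sz, ra)
                for bi, band in enumerate(bands):
                    rho_a[i, j, k, :, bi] = atm.path_reflectance(tau, g, band)
                    trans[i, j, k, :, bi] = atm.transmittance_product(tau, g, band)
                    sph[i, j, k, :, bi] = atm.spherical_albedo(tau, band)
    lut = LookupTable(axes=axes, rho_a=rho_a, trans=trans, sph_alb=sph)
    lut.validate()
    return lut


def _check_span(lut: LookupTable, geom: ViewGeometry, tau550) -> None:
    queries = {
        "satellite_zenith": np.asarray(geom.satellite_zenith),
        "solar_zenith": np.asarray(geom.solar_zenith),
        "relative_azimuth": np.asarray(geom.relative_azimuth),
        "tau550": np.asarray(tau550),
    }
    for name, q in queries.items():
        ax = np.asarray(lut.axes[name], dtype=float)
        if np.any(q < ax[0]) or np.any(q > ax[-1]):
            raise ValueError(
                f"query outside LUT span on axis {name!r}: "
                f"allowed [{ax[0]}, {ax[-1]}]"
            )


def interpolate_lut(lut: LookupTable, geom: ViewGeometry, tau550, band: int):
    """Multi-linear interpolation of (ρa, T, s) at an in-span query.

    Exact at LUT nodes; raises naming the offending axis when out of span.
    """
    _check_span(lut, geom, tau550)
    bi = lut.band_index(band)
    tau = np.atleast_1d(np.asarray(tau550, dtype=float))
    pts = np.column_stack([
        np.full_like(tau, geom.satellite_zenith),
        np.full_like(tau, geom.solar_zenith),
        np.full_like(tau, geom.relative_azimuth),
        tau,
    ])
    out = tuple(
        lut._interp(name, table)[bi](pts)
        for name, table in (("rho_a", lut.rho_a), ("trans", lut.trans), ("sph_alb", lut.sph_alb))
    )
    if np.isscalar(tau550) or np.ndim(tau550) == 0:
        return tuple(float(o[0]) for o in out)
    return out


def atm_node_curves(lut: LookupTable, geom: ViewGeometry, band: int):
    """(ρa, T, s) at every τ node for a fixed (interpolated) geometry.

    The LUT being multilinear, the forward curve between consecutive τ nodes
    is exactly linear; these node curves are all the inversion needs.
    """
    tau_axis = np.asarray(lut.axes["tau550"], dtype=float)
    rho_a, trans, sph = interpolate_lut(lut, geom, tau_axis, band)
    return tau_axis, np.asarray(rho_a), np.asarray(trans), np.asarray(sph)
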