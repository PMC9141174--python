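"""Ground-truth collocation and verification statistics.

Sun-photometer networks report AOD at channels such as 440/675/870 nm but not
at the 550 nm retrieval wavelength, so multi-wavelength ground AOD is moved to
550 nm through the Angstrom law τ(λ) = β·λ^−α (λ in µm). Retrieval grids are
then collocated with ground records (exact cell, exact calendar day) and
compared with Pearson and Spearman correlation plus mean/standard deviation
summaries.

A 21-record collocation table from a 2016 coastal retrieval campaign
(two sun-photometer sites) ships with the package as a worked verification
fixture; see :func:`load_reference_collocation`.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from scipy.stats import rankdata

from .grid import AODField
from .seasons import season_of_date
from .synthetic import StationNetwork


# ---------------------------------------------------------------------------
# Angstrom wavelength conversion

def fit_angstrom(wavelengths_nm, tau) -> tuple[float, float]:
    """Fit (α, β) of τ(λ) = β·(λ/µm)^−α by log-log least squares.

    Exact when the data lie on a power law. Requires ≥ 2 distinct
    wavelengths and strictly positive optical depths.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if lam.shape != tau.shape or lam.ndim != 1:
        raise ValueError("wavelengths and tau must be 1-D and equal length")
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be positive")
    if np.any(tau <= 0):
        raise ValueError("optical depths must be positive for the log-log fit")
    if len(np.unique(lam)) < 2:
        raise ValueError("need at least 2 distinct wavelengths")
    lam_um = lam / 1000.0
    design = np.column_stack([np.ones_like(lam_um), np.log(lam_um)])
    sol, _, _, _ = np.linalg.lstsq(design, np.log(tau), rcond=None)
    ln_beta, neg_alpha = sol
    return float(-neg_alpha), float(np.exp(ln_beta))


def angstrom_interpolate(alpha: float, beta: float, target_lambda_nm: float) -> float:
    """τ at a target wavelength from fitted Angstrom parameters."""
    if target_lambda_nm <= 0:
        raise ValueError("wavelength must be positive")
    return float(beta * (target_lambda_nm / 1000.0) ** (-alpha))


def spectral_to_550(wavelengths_nm, tau) -> float:
    """Convenience: fit the Angstrom law and evaluate at 550 nm."""
    alpha, beta = fit_angstrom(wavelengths_nm, tau)
    return angstrom_interpolate(alpha, beta, 550.0)


# ---------------------------------------------------------------------------
# Collocation

def collocate(fields, network: StationNetwork, observations: pd.DataFrame,
              kind: str | None = None) -> pd.DataFrame:
    """Pair gridded retrievals with ground observations.

    ``fields`` is a mapping date → AODField/array (or a single field applied
    to every observation date). One pair per (station, date) where the field
    cell is valid and a ground value exists; cloud-masked cells drop out.
    Returns columns (date, station_id, x, y, season), x = grid value.
    """
    stations = network.of_kind(kind) if kind else network.stations
    by_id = stations.set_index("station_id")
    rows = []
    for _, obs in observations.iterrows():
        sid, date = obs["station_id"], str(obs["date"])
        if sid not in by_id.index:
            continue
        field = fields[date] if isinstance(fields, dict) else fields
        if field is None:
            continue
        grid = field.tau550 if isinstance(field, AODField) else np.asarray(field, dtype=float)
        r, c = int(by_id.loc[sid, "row"]), int(by_id.loc[sid, "col"])
        if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
            raise ValueError(f"station {sid} outside the grid")
        x = grid[r, c]
        if np.isfinite(x) and np.isfinite(obs["value"]):
            rows.append((date, sid, float(x), float(obs["value"]), season_of_date(date)))
    return pd.DataFrame(rows, columns=["date", "station_id", "x", "y", "season"])


# ---------------------------------------------------------------------------
# Verification statistics

def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; rejects degenerate margins."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = np.sum(dx ** 2), np.sum(dy ** 2)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in a margin: correlation undefined")
    return float(np.sum(dx * dy) / np.sqrt(sxx * syy))


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided t-distribution p-value for a Pearson correlation."""
    if n < 3:
        raise ValueError("need n >= 3 for a p-value")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return float(2 * _sstats.t.sf(abs(t), n - 2))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation.

    Without ties this is the classic shortcut 1 − 6Σd²/(n(n²−1)); with ties
    it falls back to the Pearson correlation of mid-ranks (the shortcut is a
    no-ties identity, not a definition).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("all values identical in a margin: ranks undefined")
    gx, gy = rankdata(x), rankdata(y)
    n = len(x)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if not ties:
        d = gx - gy
        return float(1.0 - 6.0 * np.sum(d ** 2) / (n * (n ** 2 - 1)))
    return pearson_r(gx, gy)


def summary_stats(values) -> tuple[float, float]:
    """(mean, sample standard deviation) — SD uses the n−1 denominator."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("need a non-empty 1-D sample")
    if len(v) < 2:
        raise ValueError("need n >= 2 for a standard deviation")
    return float(v.mean()), float(v.std(ddof=1))


@dataclass
class ValidationReport:
    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    pearson: float
    pearson_p: float
    spearman: float

    def as_dict(self) -> dict:
        return dict(n=self.n, mean_x=self.mean_x, sd_x=self.sd_x,
                    mean_y=self.mean_y, sd_y=self.sd_y, pearson=self.pearson,
                    pearson_p=self.pearson_p, spearman=self.spearman)


def validate_pairs(pairs: pd.DataFrame, x_col: str = "x", y_col: str = "y") -> ValidationReport:
    """Full verification summary for a paired table."""
    x = pairs[x_col].to_numpy(dtype=float)
    y = pairs[y_col].to_numpy(dtype=float)
    mx, sx = summary_stats(x)
    my, sy = summary_stats(y)
    r = pearson_r(x, y)
    return ValidationReport(len(x), mx, sx, my, sy, r,
                            pearson_p_value(r, len(x)), spearman_rho(x, y))


def load_reference_collocation() -> pd.DataFrame:
    """The packaged 21-row retrieval-vs-ground collocation table.

    Columns: site, date, inversion_aod, observation_aod (dimensionless AOD).
    """
    with _resources.files("hazegrid.data").joinpath(
            "aeronet_collocation_2016.csv").open() as fh:
        return pd.read_csv(fh)
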