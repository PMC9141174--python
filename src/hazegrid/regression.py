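"""Seasonal AOD-PM2.5 regression: six model families, selection, prediction.

PM2.5 mass concentration (µg/m³) is regressed on aerosol optical depth per
season using six candidate families — linear, logarithmic, exponential, power,
quadratic and cubic. Exponential and power fits are done by least squares
after log transformation (exact for noise-free power/exponential data);
an optional iterative refinement minimises the untransformed residual.
The best family is chosen on a chronologically later verification split by
verification R², ties broken by RMSE, then by parsimony.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .seasons import SEASONS

#: family name → number of coefficients (a0..a_{k-1})
FAMILIES: dict[str, int] = {
    "linear": 2,
    "logarithmic": 2,
    "exponential": 2,
    "power": 2,
    "quadratic": 3,
    "cubic": 4,
}

#: families whose predictor domain is x > 0
_POSITIVE_X = ("logarithmic", "power")
#: families fitted on log-transformed y
_POSITIVE_Y = ("exponential", "power")


def evaluate_family(family: str, coeffs, x):
    """Evaluate a model family at x (vectorised); out-of-domain x → NaN."""
    c = np.asarray(coeffs, dtype=float)
    x = np.asarray(x, dtype=float)
    if family == "linear":
        return c[0] + c[1] * x
    if family == "logarithmic":
        out = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
        return c[0] + c[1] * out
    if family == "exponential":
        return c[0] * np.exp(c[1] * x)
    if family == "power":
        out = np.where(x > 0, np.power(np.where(x > 0, x, 1.0), c[1]), np.nan)
        return c[0] * out
    if family == "quadratic":
        return c[0] + c[1] * x + c[2] * x ** 2
    if family == "cubic":
        return c[0] + c[1] * x + c[2] * x ** 2 + c[3] * x ** 3
    raise ValueError(f"unknown family {family!r}; known: {sorted(FAMILIES)}")


@dataclass
class FittedModel:
    """One fitted AOD→PM2.5 relation with its diagnostics.

    ``x_bounds`` holds frozen min-max normalisation bounds for the predictor
    when normalisation was requested at fit time (None = raw AOD).
    """

    family: str
    coefficients: tuple
    season: str = ""
    diagnostics: dict = dc_field(default_factory=dict)
    x_bounds: tuple | None = None

    @property
    def n_coefficients(self) -> int:
        return FAMILIES[self.family]

    def _transform(self, x):
        if self.x_bounds is None:
            return np.asarray(x, dtype=float)
        return minmax_normalize(x, bounds=self.x_bounds)

    def predict(self, x):
        return evaluate_family(self.family, self.coefficients, self._transform(x))

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "coefficients": list(self.coefficients),
            "season": self.season,
            "diagnostics": self.diagnostics,
            "x_bounds": list(self.x_bounds) if self.x_bounds else None,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(d["family"], tuple(d["coefficients"]), d.get("season", ""),
                   d.get("diagnostics", {}),
                   tuple(d["x_bounds"]) if d.get("x_bounds") else None)


def minmax_normalize(values, bounds: tuple | None = None):
    """Min-max rescale to [0, 1]; order preserving.

    With ``bounds=(lo, hi)`` the rescaling is frozen (used to apply the
    build-set normalisation to verification and prediction data).
    """
    v = np.asarray(values, dtype=float)
    if bounds is None:
        finite = v[np.isfinite(v)]
        if finite.size == 0:
            raise ValueError("cannot normalize an all-missing sample")
        lo, hi = float(finite.min()), float(finite.max())
    else:
        lo, hi = map(float, bounds)
    if hi <= lo:
        raise ValueError("constant input: max must exceed min for min-max normalization")
    return (v - lo) / (hi - lo)


def fit_family(family: str, x, y, season: str = "", normalize_x: bool = False,
               refine: bool = False) -> FittedModel:
    """Least-squares fit of one family; exact on noise-free generating data.

    Exponential/power families are fitted on (x, ln y) / (ln x, ln y) and
    back-transformed; ``refine=True`` follows with nonlinear least squares on
    the original scale starting from the transform solution.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; known: {sorted(FAMILIES)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D samples of equal length")
    k = FAMILIES[family]
    if len(x) <= k:
        raise ValueError(f"need more than {k} samples to fit {family}")
    if family in _POSITIVE_X and np.any(x <= 0):
        raise ValueError(f"{family} family requires x > 0")
    if family in _POSITIVE_Y and np.any(y <= 0):
        raise ValueError(f"{family} family requires y > 0 (log-transform fit)")

    bounds = None
    if normalize_x:
        finite = x[np.isfinite(x)]
        bounds = (float(finite.min()), float(finite.max()))
        x = minmax_normalize(x, bounds=bounds)
        if family in _POSITIVE_X and np.any(x <= 0):
            raise ValueError(f"{family} family requires x > 0 after normalization")

    if family in ("linear", "quadratic", "cubic"):
        deg = k - 1
        design = np.vander(x, deg + 1, increasing=True)
        coeffs = _solve(design, y)
    elif family == "logarithmic":
        design = np.column_stack([np.ones_like(x), np.log(x)])
        coeffs = _solve(design, y)
    elif family == "exponential":
        design = np.column_stack([np.ones_like(x), x])
        b = _solve(design, np.log(y))
        coeffs = np.array([np.exp(b[0]), b[1]])
    else:  # power
        design = np.column_stack([np.ones_like(x), np.log(x)])
        b = _solve(design, np.log(y))
        coeffs = np.array([np.exp(b[0]), b[1]])

    if refine and family in _POSITIVE_Y:
        def f(xx, a0, a1):
            return evaluate_family(family, (a0, a1), xx)
        try:
            coeffs, _ = curve_fit(f, x, y, p0=coeffs, maxfev=10000)
        except RuntimeError:
            pass  # keep the transform solution

    model = FittedModel(family, tuple(float(c) for c in coeffs), season, {}, bounds)
    r2, f_stat = goodness(model, x if bounds is None else _denorm(x, bounds), y)
    model.diagnostics.update({"r2_build": r2, "f_build": f_stat, "n_build": int(len(x))})
    return model


def _denorm(xn, bounds):
    lo, hi = bounds
    return xn * (hi - lo) + lo


def _solve(design: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("singular design matrix (degenerate predictor sample)")
    return sol


def goodness(model: FittedModel, x, y) -> tuple[float, float]:
    """(R², F) on the original y scale.

    R² = 1 − SSE/SStot (equals explained-variance-over-total for ordinary
    linear least squares, and is bounded by 1 for every family); the F
    statistic uses p = number of predictor terms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yhat = model.predict(x)
    ok = np.isfinite(yhat) & np.isfinite(y)
    y, yhat = y[ok], yhat[ok]
    p = model.n_coefficients - 1
    n = len(y)
    if n <= p + 1:
        raise ValueError("too few samples for goodness-of-fit")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero total sum of squares: response is constant")
    sse = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - sse / sst
    denom = (1.0 - r2) / (n - p - 1)
    f_stat = float("inf") if denom <= 0 else (r2 / p) / denom
    return r2, f_stat


def rmse(model: FittedModel, x, y) -> float:
    """Root mean squared prediction error, n denominator, in y units (µg/m³)."""
    yhat = model.predict(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(yhat) & np.isfinite(y)
    if ok.sum() == 0:
        return float("nan")
    return float(np.sqrt(np.mean((yhat[ok] - y[ok]) ** 2)))


@dataclass
class SeasonalSplit:
    build: pd.DataFrame
    verify: pd.DataFrame
    eliminated: pd.DataFrame


def split_by_season(pairs: pd.DataFrame, build_fraction: float = 0.7,
                    build_counts: dict | None = None,
                    outlier_rule: str | None = "resid3") -> dict[str, SeasonalSplit]:
    """Chronological build/verify split per season with optional outlier removal.

    ``pairs`` needs columns (date, season, x, y). The earliest records form
    the build set (``build_counts[season]`` rows if given, else the build
    fraction); under ``outlier_rule="resid3"`` verification rows whose
    absolute standardized residual under the best preliminary build fit
    exceeds 3 are eliminated (and reported, not silently dropped).
    """
    out: dict[str, SeasonalSplit] = {}
    for season, grp in pairs.groupby("season"):
        grp = grp.sort_values(["date", "station_id"] if "station_id" in grp else ["date"],
                              kind="mergesort").reset_index(drop=True)
        n = len(grp)
        n_build = int(build_counts[season]) if build_counts else int(round(n * build_fraction))
        if n_build < 5 or n - n_build < 5:
            raise ValueError(f"season {season!r}: too few rows ({n}) to split")
        build = grp.iloc[:n_build]
        verify = grp.iloc[n_build:]
        eliminated = verify.iloc[0:0]
        if outlier_rule == "resid3":
            best = _best_preliminary(build)
            if best is not None:
                resid = verify["y"].to_numpy() - best.predict(verify["x"].to_numpy())
                scale = rmse(best, build["x"].to_numpy(), build["y"].to_numpy())
                if scale > 0:
                    bad = np.abs(resid) / scale > 3.0
                    bad &= np.isfinite(resid)
                    eliminated = verify[bad]
                    verify = verify[~bad]
        elif outlier_rule is not None:
            raise ValueError(f"unknown outlier rule {outlier_rule!r}")
        out[season] = SeasonalSplit(build.reset_index(drop=True),
                                    verify.reset_index(drop=True),
                                    eliminated.reset_index(drop=True))
    return out


def _best_preliminary(build: pd.DataFrame) -> FittedModel | None:
    x, y = build["x"].to_numpy(), build["y"].to_numpy()
    best, best_r2 = None, -np.inf
    for family in FAMILIES:
        try:
            m = fit_family(family, x, y)
        except ValueError:
            continue
        if m.diagnostics["r2_build"] > best_r2:
            best, best_r2 = m, m.diagnostics["r2_build"]
    return best


def fit_all_families(x, y, season: str = "", normalize_x: bool = False,
                     families=None) -> list[FittedModel]:
    """Fit every requested family, skipping those whose domain the data violate."""
    models = []
    for family in (families or FAMILIES):
        try:
            models.append(fit_family(family, x, y, season, normalize_x))
        except ValueError:
            continue
    if not models:
        raise ValueError("no candidate family could be fitted")
    return models


def select_model(candidates: list[FittedModel], x_verify, y_verify,
                 tie_tolerance: float = 0.01) -> FittedModel:
    """Pick the best candidate on the verification split.

    Candidates are scored by verification R² (equivalently RMSE — the two
    order identically on a common verification set). Scores within
    ``tie_tolerance`` of the best are treated as tied, and ties go to the
    model with fewer coefficients, then lower RMSE: among near-equal fits a
    flexible polynomial tracking noise should not displace a simpler law
    (the one-standard-error idea from cross-validation). Diagnostics are
    written back onto every candidate.
    """
    if not candidates:
        raise ValueError("no candidate models")
    x_verify = np.asarray(x_verify, dtype=float)
    y_verify = np.asarray(y_verify, dtype=float)
    for m in candidates:
        try:
            r2v, _ = goodness(m, x_verify, y_verify)
        except ValueError:
            r2v = -np.inf
        m.diagnostics["r2_verify"] = r2v
        m.diagnostics["rmse_verify"] = rmse(m, x_verify, y_verify)
    best_r2 = max(m.diagnostics["r2_verify"] for m in candidates)
    near = [m for m in candidates
            if m.diagnostics["r2_verify"] >= best_r2 - tie_tolerance]
    return min(near, key=lambda m: (m.n_coefficients,
                                    m.diagnostics["rmse_verify"]))


def predict_grid(model: FittedModel, aod: np.ndarray) -> np.ndarray:
    """Map an AOD grid to PM2.5 (µg/m³) cellwise.

    Nodata propagates; x ≤ 0 under power/logarithmic families → nodata;
    negative predictions are floored at 0.
    """
    aod = np.asarray(aod, dtype=float)
    out = np.full(aod.shape, np.nan)
    ok = np.isfinite(aod)
    if model.family in _POSITIVE_X:
        ok &= aod > 0
    vals = model.predict(aod[ok])
    out[ok] = np.maximum(vals, 0.0)
    return out
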