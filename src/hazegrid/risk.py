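"""Relative population exposure risk to PM2.5 and six-level classification.

The per-cell relative risk is Q_i = P_i·M_i / mean(P·M) with P the population
density (persons/km²) and M the PM2.5 concentration (µg/m³); the mean runs
over valid cells, so mean(Q) = 1 by construction and Q is invariant to any
positive rescaling of either input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec
from .synthetic import PopulationGrid

#: six-level classification, codes 0..5; intervals are (a, b] except level 0
RISK_LEVELS = (
    "extremely safe",       # Q = 0
    "safe",                 # 0 < Q <= 1
    "relatively safe",      # 1 < Q <= 2
    "relatively dangerous", # 2 < Q <= 3
    "dangerous",            # 3 < Q <= 5
    "extremely dangerous",  # Q > 5
)
_LEVEL_EDGES = (0.0, 1.0, 2.0, 3.0, 5.0)
LEVEL_NODATA = -1


@dataclass
class RiskGrid:
    q: np.ndarray          # relative risk, NaN = nodata
    level: np.ndarray      # int codes 0..5, LEVEL_NODATA where q is nodata
    spec: GridSpec


def relative_risk(pm25: np.ndarray, population: PopulationGrid | np.ndarray,
                  spec: GridSpec | None = None) -> RiskGrid:
    """Q_i = P_i·M_i / mean over valid cells of P·M.

    Cells are valid only where both inputs are valid; rejects inputs whose
    exposure products are all zero (undefined normalisation).
    """
    if isinstance(population, PopulationGrid):
        pop, spec = population.density, population.spec
    else:
        pop = np.asarray(population, dtype=float)
        if spec is None:
            raise ValueError("spec required when population is a bare array")
    pm25 = np.asarray(pm25, dtype=float)
    if pm25.shape != pop.shape or pm25.shape != spec.shape:
        raise ValueError("PM2.5 and population grids must share one grid spec")
    valid = np.isfinite(pm25) & np.isfinite(pop)
    if not valid.any():
        raise ValueError("no cell valid in both inputs")
    prod = np.where(valid, pm25 * pop, np.nan)
    mean_prod = np.nanmean(prod)
    if mean_prod <= 0:
        raise ValueError("all exposure products are zero: risk undefined")
    q = prod / mean_prod
    return RiskGrid(q, classify(q), spec)


def classify(q: np.ndarray) -> np.ndarray:
    """Six-level codes from Q: 0 ↦ level 0; (0,1] ↦ 1; (1,2] ↦ 2; (2,3] ↦ 3;
    (3,5] ↦ 4; (5,∞) ↦ 5. Nodata cells get LEVEL_NODATA."""
    q = np.asarray(q, dtype=float)
    if np.any(q[np.isfinite(q)] < 0):
        raise ValueError("risk values must be non-negative")
    level = np.full(q.shape, LEVEL_NODATA, dtype=int)
    ok = np.isfinite(q)
    # searchsorted with side="left" makes each interval closed on the right
    level[ok] = np.searchsorted(_LEVEL_EDGES, q[ok], side="left")
    return level


def aggregate_regions(risk: RiskGrid, regions: np.ndarray) -> pd.DataFrame:
    """Unweighted mean Q per region label.

    ``regions`` is a label grid aligned with the risk grid (NaN/negative =
    outside). Regions with no valid risk cell are reported with NaN mean.
    """
    regions = np.asarray(regions)
    if regions.shape != risk.q.shape:
        raise ValueError("region labels must align with the risk grid")
    lab = regions.ravel()
    q = risk.q.ravel()
    inside = np.isfinite(lab.astype(float)) & (lab.astype(float) >= 0)
    if not inside.any():
        raise ValueError("no overlap between regions and the grid")
    df = pd.DataFrame({"region": lab[inside], "q": q[inside]})
    grouped = df.groupby("region")["q"].agg(
        mean_q="mean", n_valid=lambda s: int(s.notna().sum()))
    if not (np.isfinite(df["q"]).any()):
        raise ValueError("no valid risk cell inside any region")
    return grouped.reset_index()
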