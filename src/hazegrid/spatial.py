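"""Global and local Moran's I on raster grids, with LISA cluster mapping.

Spatial weights are rook (4-neighbour) or queen (8-neighbour) contiguity
among valid cells, optionally row-standardized; nodata cells are removed from
the weight graph entirely. Inference is by conditional permutation: each
cell's value is held fixed while the remaining values are reassigned among
the other cells, the standard randomisation scheme for local statistics.

Cluster labels: HH/LL for significant high-value/low-value agglomeration,
HL/LH for significant spatial outliers, NS otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

#: LISA cluster codes
CLUSTER_NS, CLUSTER_HH, CLUSTER_LL, CLUSTER_LH, CLUSTER_HL = 0, 1, 2, 3, 4
CLUSTER_NAMES = {0: "NS", 1: "HH", 2: "LL", 3: "LH", 4: "HL"}

_OFFSETS = {
    "rook": ((-1, 0), (1, 0), (0, -1), (0, 1)),
    "queen": ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)),
}


@dataclass
class WeightMatrix:
    """Contiguity weights over the valid cells of a raster grid."""

    w: sparse.csr_matrix
    cells: np.ndarray            # (n, 2) row/col of valid cells, row-major order
    grid_shape: tuple[int, int]
    scheme: str
    standardization: str
    cardinality: np.ndarray      # neighbour counts (pre-standardization)

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def islands(self) -> np.ndarray:
        """Cells with no neighbour; flagged and excluded from statistics."""
        return self.cardinality == 0

    def compact(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        if grid.shape != self.grid_shape:
            raise ValueError("grid shape does not match the weight matrix")
        return grid[self.cells[:, 0], self.cells[:, 1]]

    def expand(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(self.grid_shape, fill, dtype=np.asarray(values).dtype
                      if np.asarray(values).dtype.kind == "f" else float)
        out[self.cells[:, 0], self.cells[:, 1]] = values
        return out


def build_weights(valid_mask: np.ndarray, scheme: str = "queen",
                  standardization: str = "row") -> WeightMatrix:
    """Contiguity weight matrix among valid cells (no self-neighbours)."""
    if scheme not in _OFFSETS:
        raise ValueError("scheme must be 'rook' or 'queen'")
    if standardization not in ("row", "binary"):
        raise ValueError("standardization must be 'row' or 'binary'")
    valid = np.asarray(valid_mask, dtype=bool)
    n = int(valid.sum())
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    idx = np.full(valid.shape, -1, dtype=int)
    idx[valid] = np.arange(n)
    rows_i, cols_j, rr, cc = [], [], *np.nonzero(valid)
    for dr, dc in _OFFSETS[scheme]:
        r2, c2 = rr + dr, cc + dc
        ok = (r2 >= 0) & (r2 < valid.shape[0]) & (c2 >= 0) & (c2 < valid.shape[1])
        ok &= valid[r2 % valid.shape[0], c2 % valid.shape[1]] & ok
        rows_i.append(idx[rr[ok], cc[ok]])
        cols_j.append(idx[r2[ok], c2[ok]])
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    w = sparse.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    card = np.asarray(w.sum(axis=1)).ravel().astype(int)
    if (card == 0).all():
        raise ValueError("all cells are isolated under this scheme")
    if standardization == "row":
        inv = np.divide(1.0, card, out=np.zeros(n, dtype=float), where=card > 0)
        w = sparse.diags(inv) @ w
    cells = np.column_stack([rr, cc])
    return WeightMatrix(w.tocsr(), cells, valid.shape, scheme, standardization, card)


def _as_compact(x, w: WeightMatrix) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        return w.compact(x)
    if x.shape != (w.n,):
        raise ValueError("x must be a grid or a compact vector aligned with w")
    return x


def global_morans_i(x, w: WeightMatrix, n_perm: int = 0, seed: int | None = None):
    """Global Moran's I; with ``n_perm`` > 0 also a one-sided permutation p.

    I = (n/S0)·Σij wij(xi−x̄)(xj−x̄)/Σi(xi−x̄)², computed over non-isolated
    cells. Rejects zero-variance inputs.
    """
    x = _as_compact(x, w)
    keep = ~w.islands
    xs = x[keep]
    ws = w.w[keep][:, keep]
    n = len(xs)
    z = xs - xs.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("zero variance: Moran's I undefined")
    s0 = float(ws.sum())
    i_obs = (n / s0) * float(z @ (ws @ z)) / ss
    if n_perm <= 0:
        return i_obs
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        i_star = (n / s0) * float(zp @ (ws @ zp)) / ss
        if i_star >= i_obs:
            count += 1
    return i_obs, (count + 1) / (n_perm + 1)


def local_morans_i(x, w: WeightMatrix) -> np.ndarray:
    """Local Moran's I_i = (x_i−x̄)/S² · Σj w_ij (x_j−x̄), S² the sample
    variance (n−1 denominator). Isolated cells get NaN.

    Sum identity: Σ I_i = I_global · S0·(n−1)/n.
    """
    x = _as_compact(x, w)
    keep = ~w.islands
    xs = x[keep]
    n = len(xs)
    z = xs - xs.mean()
    s2 = float(z @ z) / (n - 1)
    if s2 == 0:
        raise ValueError("zero variance: local Moran's I undefined")
    lag = np.asarray(w.w[keep][:, keep] @ z)
    out = np.full(w.n, np.nan)
    out[keep] = z / s2 * lag
    return out


def permutation_p(x, w: WeightMatrix, n_perm: int = 999,
                  seed: int | None = None) -> np.ndarray:
    """Two-sided conditional-permutation p-values for local Moran's I.

    Per cell, x_i stays fixed and its neighbours draw values (without
    replacement) from the other cells; p = (#{|I*| ≥ |I_i|} + 1)/(n_perm+1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    x = _as_compact(x, w)
    keep = ~w.islands
    keep_idx = np.flatnonzero(keep)
    xs = x[keep]
    n = len(xs)
    z = xs - xs.mean()
    s2 = float(z @ z) / (n - 1)
    if s2 == 0:
        raise ValueError("zero variance")
    obs = local_morans_i(x, w)
    rng = np.random.default_rng(seed)
    k_max = int(w.cardinality[keep].max())
    if k_max >= n:
        raise ValueError("a cell has more neighbours than available donors")
    # one (n_perm × k_max) without-replacement index matrix shared by all cells
    draw = np.argsort(rng.random((n_perm, n - 1)), axis=1)[:, :k_max]
    wsub = w.w[keep][:, keep].tocsr()
    p = np.full(w.n, np.nan)
    ids = np.arange(n)
    for pos, i in enumerate(keep_idx):
        start, end = wsub.indptr[pos], wsub.indptr[pos + 1]
        k = end - start
        if k == 0:
            continue
        weights = wsub.data[start:end]
        donors = ids[ids != pos]
        rng.shuffle(donors)
        sampled = z[donors[draw[:, :k]]]           # (n_perm, k)
        lag_star = sampled @ weights
        i_star = z[pos] / s2 * lag_star
        exceed = int(np.sum(np.abs(i_star) >= abs(obs[i]) - 1e-14))
        p[i] = (exceed + 1) / (n_perm + 1)
    return p


def lisa_classify(x, local_i, p, alpha: float, w: WeightMatrix) -> np.ndarray:
    """Cluster codes: NS where p > α; else the quadrant of
    (x_i − x̄, spatial lag − lag mean): HH, LL, LH (low amid high), HL."""
    x = _as_compact(x, w)
    local_i = np.asarray(local_i, dtype=float)
    p = np.asarray(p, dtype=float)
    keep = ~w.islands
    xs = x[keep]
    z = xs - xs.mean()
    lag = np.asarray(w.w[keep][:, keep] @ xs)
    lag_dev = lag - lag.mean()
    codes = np.full(w.n, CLUSTER_NS, dtype=int)
    sig = np.zeros(w.n, dtype=bool)
    sig[keep] = np.isfinite(p[keep]) & (p[keep] <= alpha)
    quad = np.full(w.n, CLUSTER_NS, dtype=int)
    sub = np.where(z > 0, np.where(lag_dev > 0, CLUSTER_HH, CLUSTER_HL),
                   np.where(lag_dev > 0, CLUSTER_LH, CLUSTER_LL))
    quad[keep] = sub
    codes[sig] = quad[sig]
    return codes


@dataclass
class LISAResult:
    """Local Moran grids: statistic, permutation p, cluster codes."""

    local_i: np.ndarray
    p: np.ndarray
    cluster: np.ndarray   # int codes, CLUSTER_* ; NS on nodata cells
    global_i: float
    weights: WeightMatrix


def lisa(grid: np.ndarray, scheme: str = "queen", alpha: float = 0.05,
         n_perm: int = 999, seed: int | None = None,
         standardization: str = "row") -> LISAResult:
    """One-call LISA analysis of a raster grid (NaN = nodata)."""
    grid = np.asarray(grid, dtype=float)
    valid = np.isfinite(grid)
    w = build_weights(valid, scheme=scheme, standardization=standardization)
    x = w.compact(grid)
    li = local_morans_i(x, w)
    p = permutation_p(x, w, n_perm=n_perm, seed=seed)
    codes = lisa_classify(x, li, p, alpha, w)
    gi = global_morans_i(x, w)
    return LISAResult(w.expand(li), w.expand(p),
                      w.expand(codes.astype(float), fill=float(CLUSTER_NS)).astype(int),
                      gi, w)
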