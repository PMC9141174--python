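"""Regular 1-km analysis grids and GeoTIFF raster I/O.

All in-memory rasters are float64 numpy arrays in which ``NaN`` marks nodata.
On disk, rasters are float32 GeoTIFFs with nodata −9999 and a minimal
georeferencing tag set (pixel scale + tiepoint), so they open in any GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile

NODATA = -9999.0

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """A regular raster grid: 0-based, row-major, top-left origin.

    ``cell_size_km`` is the edge length of a (square) cell; the analysis
    resolution throughout is 1 km × 1 km.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 1.0
    origin_row_col: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def mask_nodata(values: np.ndarray, nodata: float = NODATA) -> np.ndarray:
    """Replace a sentinel nodata value by NaN (returns float64 copy)."""
    out = np.asarray(values, dtype=float).copy()
    out[out == nodata] = np.nan
    return out


def write_grid(path, bands, spec: GridSpec, band_names: Sequence[str] | None = None) -> None:
    """Write one or more grids to a float32 GeoTIFF (nodata −9999).

    ``bands`` may be a single 2-D array or a sequence of 2-D arrays; all must
    match ``spec.shape``. NaN cells are stored as −9999.
    """
    arrs = [np.asarray(bands)] if np.ndim(bands) == 2 else [np.asarray(b) for b in bands]
    for a in arrs:
        if a.shape != spec.shape:
            raise ValueError(
                f"band shape {a.shape} does not match grid {spec.shape}"
            )
    stack = np.stack(arrs).astype(np.float32)
    stack = np.where(np.isnan(stack), np.float32(NODATA), stack)
    cs = float(spec.cell_size_km)
    oy, ox = spec.origin_row_col
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox * cs, oy * cs, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(int(NODATA))),
    ]
    with tifffile.TiffWriter(path) as tif:
        for page in stack:
            tif.write(page, extratags=extratags, description=";".join(band_names or []))


def read_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read a GeoTIFF written by :func:`write_grid`.

    Returns ``(values, spec)``; ``values`` has shape (n_rows, n_cols) for a
    single band or (n_bands, n_rows, n_cols) otherwise, with nodata as NaN.
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        tags = tif.pages[0].tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else (0.0,) * 6
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError("mismatched band shapes in multi-band stack")
    cs = float(scale[0])
    origin = (int(round(tie[4] / cs)), int(round(tie[3] / cs)))
    arr = np.stack([mask_nodata(p) for p in pages])
    spec = GridSpec(arr.shape[1], arr.shape[2], cs, origin)
    return (arr[0] if arr.shape[0] == 1 else arr), spec


@dataclass
class AODField:
    """A grid of aerosol optical depth at 550 nm (dimensionless, [0, 1.95]).

    NaN marks cloud-masked or unretrievable cells. ``period`` labels the
    date or the monthly/seasonal compositing period.
    """

    tau550: np.ndarray
    spec: GridSpec
    period: str = ""

    def __post_init__(self) -> None:
        self.tau550 = np.asarray(self.tau550, dtype=float)
        if self.tau550.shape != self.spec.shape:
            raise ValueError("tau550 shape does not match grid spec")
        valid = self.tau550[np.isfinite(self.tau550)]
        if valid.size and (valid.min() < 0 or valid.max() > 1.95):
            raise ValueError("AOD values must lie in [0, 1.95]")
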