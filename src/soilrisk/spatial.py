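"""Gridded layers, ESRI ASCII grid I/O, and inverse-distance interpolation.

All coordinates are projected meters.  Grids use an upper-left origin with
row-major storage; cell values are evaluated/extracted at cell centers.
Cell membership is half-open: ``[left, right)`` in x and ``(top, bottom]``
in y, so a point on a shared edge belongs to exactly one cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RasterLayer",
    "idw_interpolate",
    "extract_at_points",
    "read_raster",
    "write_raster",
]

#: Distance (m) below which a cell center is considered coincident with a point.
EXACT_HIT_TOL = 1e-9


@dataclass
class RasterLayer:
    """A regular grid with georeferencing.

    ``origin`` is the projected (x, y) of the grid's *upper-left corner*;
    ``values`` is an ``(nrows, ncols)`` array; ``nodata`` is the sentinel
    for missing cells; ``kind`` is ``"continuous"`` or ``"categorical"``.
    """

    origin: Tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0
    kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown raster kind {self.kind!r}")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        v = self.values
        mask = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= ~np.isnan(v)
        return mask

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinates, each shaped (nrows, ncols)."""
        x0, y0 = self.origin
        cs = self.cell_size
        xs = x0 + (np.arange(self.ncols) + 0.5) * cs
        ys = y0 - (np.arange(self.nrows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "RasterLayer":
        return replace(self, values=values, kind=kind or self.kind)


def idw_interpolate(
    points: Sequence[Tuple[float, float, float]] | np.ndarray,
    grid: RasterLayer,
    power: float = 2.0,
    k_neighbors: int = 12,
) -> RasterLayer:
    """Inverse-distance-weighted interpolation of point values onto ``grid``.

    Each cell center receives ``sum(w_j v_j) / sum(w_j)`` over its
    ``k_neighbors`` nearest points, with ``w_j = d_j ** -power``.  A cell
    whose center lies within ``EXACT_HIT_TOL`` of a point takes that
    point's value exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("points must be a nonempty (N, 3) array of (x, y, value)")
    if power <= 0:
        raise ValueError("power must be > 0")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    n = pts.shape[0]
    if k_neighbors > n:
        warnings.warn(
            f"k_neighbors={k_neighbors} exceeds point count {n}; clamping",
            stacklevel=2,
        )
        k_neighbors = n

    tree = cKDTree(pts[:, :2])
    gx, gy = grid.cell_centers()
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    dist, idx = tree.query(centers, k=k_neighbors)
    if k_neighbors == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    vals = pts[idx, 2]

    exact = dist[:, 0] < EXACT_HIT_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        w = dist ** (-power)
        out = np.einsum("ij,ij->i", w, vals) / w.sum(axis=1)
    out[exact] = vals[exact, 0]  # overrides inf-weight NaNs at exact hits
    return grid.copy_with(out.reshape(grid.values.shape), kind="continuous")


def extract_at_points(
    raster: RasterLayer, points: Sequence[Tuple[float, float]] | np.ndarray
) -> np.ndarray:
    """Value of the cell containing each (x, y) point; nodata outside extent."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x0, y0 = raster.origin
    cs = raster.cell_size
    col = np.floor((pts[:, 0] - x0) / cs).astype(int)
    # (top, bottom] in y: a point on a cell's bottom edge belongs to that cell
    row = np.ceil((y0 - pts[:, 1]) / cs).astype(int) - 1
    inside = (col >= 0) & (col < raster.ncols) & (row >= 0) & (row < raster.nrows)
    out = np.full(pts.shape[0], raster.nodata, dtype=float)
    out[inside] = raster.values[row[inside], col[inside]]
    return out


def write_raster(raster: RasterLayer, path: str | Path) -> None:
    """Write an ESRI ASCII grid (categorical layers as integers)."""
    path = Path(path)
    x0, y0 = raster.origin
    yll = y0 - raster.nrows * raster.cell_size
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    fmt = "%d" if raster.kind == "categorical" else "%.17g"
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt=fmt)


def read_raster(path: str | Path, kind: str = "continuous") -> RasterLayer:
    """Read an ESRI ASCII grid; the ``nodata_value`` header is honored."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field {key!r}")
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", -9999.0)
    cs = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cs)
    if kind == "categorical":
        values = values.astype(int)
    return RasterLayer(origin=origin, cell_size=cs, values=values, nodata=nodata, kind=kind)
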