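"""Gridded isoscape container and plain-text raster I/O.

An :class:`Isoscape` couples a mean bioavailable 87Sr/86Sr surface with a
per-cell error SD on a regular grid.  Grids are stored row-major with row 0
at the top (north), the usual raster convention, and georeferenced by the
lower-left corner and a square cell size.  Rasters are read and written as
ESRI ASCII grids (``.asc``) — a plain-text format understood by every GIS —
with the mean and error surfaces in separate files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Isoscape:
    """Mean + error 87Sr/86Sr surface on a regular grid.

    ``mean`` and ``error_sd`` are ``(nrows, ncols)`` arrays with row 0 at the
    top; invalid cells are NaN in ``mean`` (the ``valid`` mask is derived).
    ``xll, yll`` locate the lower-left corner; ``cell_size`` is the square
    cell edge in map units.  ``crs`` is a free-text coordinate-reference tag.
    """

    mean: np.ndarray
    error_sd: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cell_size: float = 1.0
    crs: str = "local"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.error_sd = np.asarray(self.error_sd, dtype=float)
        if self.mean.shape != self.error_sd.shape:
            raise ValueError("mean and error grids differ in shape")
        if self.mean.ndim != 2:
            raise ValueError("grids must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.valid
        if np.any(self.error_sd[valid] <= 0):
            raise ValueError("error_sd must be strictly positive on valid cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        return np.isfinite(self.mean) & np.isfinite(self.error_sd)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, shaped like the grid."""
        nrows, ncols = self.shape
        x = self.xll + (np.arange(ncols) + 0.5) * self.cell_size
        y = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def crop(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "Isoscape":
        """Sub-grid of cells whose centres fall in the bounding box.

        Georeferencing and nodata are preserved; idempotent for a fixed
        window.  Raises if no cell centre falls inside the window.
        """
        cx, cy = self.cell_centers()
        cols = (cx[0] >= xmin) & (cx[0] <= xmax)
        rows = (cy[:, 0] >= ymin) & (cy[:, 0] <= ymax)
        if not cols.any() or not rows.any():
            raise ValueError("crop window does not intersect the grid")
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        nrows = self.shape[0]
        return Isoscape(
            mean=self.mean[r0 : r1 + 1, c0 : c1 + 1].copy(),
            error_sd=self.error_sd[r0 : r1 + 1, c0 : c1 + 1].copy(),
            xll=self.xll + c0 * self.cell_size,
            yll=self.yll + (nrows - r1 - 1) * self.cell_size,
            cell_size=self.cell_size,
            crs=self.crs,
        )


def crop_isoscape(
    isoscape: Isoscape, window: tuple[float, float, float, float]
) -> Isoscape:
    """Functional alias for :meth:`Isoscape.crop`; ``window`` is
    ``(xmin, ymin, xmax, ymax)``."""
    return isoscape.crop(*window)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA = -9999.0


def write_ascii_grid(
    array: np.ndarray, path: str | Path, xll: float = 0.0, yll: float = 0.0,
    cell_size: float = 1.0, nodata: float = _NODATA,
) -> None:
    """Write one 2-D array (row 0 = north) as an ESRI ASCII grid."""
    arr = np.asarray(array, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {arr.shape[1]}\nnrows {arr.shape[0]}\n"
        f"xllcorner {xll}\nyllcorner {yll}\ncellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid; returns ``(array, xll, yll, cell_size)`` with
    nodata cells as NaN."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            meta[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    arr = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if arr.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError("ASCII grid data does not match declared shape")
    nodata = meta.get("nodata_value", _NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    return arr, meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0), meta.get(
        "cellsize", 1.0
    )


def write_isoscape(iso: Isoscape, mean_path: str | Path, sd_path: str | Path) -> None:
    """Write the mean and error surfaces as two ASCII grids."""
    for arr, path in ((iso.mean, mean_path), (iso.error_sd, sd_path)):
        write_ascii_grid(arr, path, iso.xll, iso.yll, iso.cell_size)


def read_isoscape(mean_path: str | Path, sd_path: str | Path,
                  crs: str = "local") -> Isoscape:
    """Read an isoscape from a pair of ASCII grids (mean, error SD)."""
    mean, xll, yll, cs = read_ascii_grid(mean_path)
    sd, xll2, yll2, cs2 = read_ascii_grid(sd_path)
    if (xll, yll, cs) != (xll2, yll2, cs2) or mean.shape != sd.shape:
        raise ValueError("mean and error grids are not aligned")
    return Isoscape(mean=mean, error_sd=sd, xll=xll, yll=yll, cell_size=cs, crs=crs)
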