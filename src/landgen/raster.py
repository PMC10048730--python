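"""Gridded surfaces and plain-text raster I/O.

Rasters are stored row-major with row 0 the northernmost row and
cell-center registration.  Missing cells are NaN.  The on-disk formats are
the ESRI ASCII grid (``.asc``, plain text) and bare TIFF (``.tif``, values
only, no projection metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np


@dataclass
class RasterSurface:
    """A rectangular grid of real values on a projected (UTM-like) plane.

    Parameters
    ----------
    values : 2-D float array; NaN marks missing cells.
    cell_size : edge length of a (square) cell in meters.
    origin : (x, y) of the *top-left corner* of the grid; row 0 is the
        northernmost row, so y decreases with increasing row index.
    tag : free-text surface name (e.g. ``"tri"``, ``"resistance"``).
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self, **changes) -> "RasterSurface":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size,
                y0 - (row + 0.5) * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of cell-center coordinates, same shape as values."""
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def snap(self, x: float, y: float) -> tuple[int, int]:
        """Nearest non-missing cell to (x, y); ties toward lower row/col."""
        nr, nc = self.shape
        if not self.missing.any():
            x0, y0 = self.origin
            col = int(np.clip(np.floor((x - x0) / self.cell_size), 0, nc - 1))
            row = int(np.clip(np.floor((y0 - y) / self.cell_size), 0, nr - 1))
            return row, col
        xs, ys = self.cell_centers()
        d2 = (xs - x) ** 2 + (ys - y) ** 2
        d2[self.missing] = np.inf
        # argmin of row-major flat index already prefers lower row, then col
        flat = int(np.argmin(d2))
        return flat // nc, flat % nc


# -- I/O ------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(raster: RasterSurface, path: str | Path) -> None:
    nr, nc = raster.shape
    x0, y0 = raster.origin
    vals = np.where(raster.missing, _NODATA, raster.values)
    header = (
        f"ncols {nc}\nnrows {nr}\n"
        f"xllcorner {x0!r}\nyllcorner {y0 - nr * raster.cell_size!r}\n"
        f"cellsize {raster.cell_size!r}\nNODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, tag: str = "") -> RasterSurface:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, dtype=float, ndmin=2)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (nr, nc):
        raise ValueError(f"grid body {vals.shape} does not match header ({nr}, {nc})")
    nodata = header.get("nodata_value", _NODATA)
    vals[vals == nodata] = np.nan
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nr * cell)
    return RasterSurface(vals, cell_size=cell, origin=origin, tag=tag)


def write_raster(raster: RasterSurface, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, raster.values.astype(np.float32))
    else:
        write_ascii_grid(raster, path)


def read_raster(path: str | Path, cell_size: float = 1.0,
                origin: tuple[float, float] = (0.0, 0.0), tag: str = "") -> RasterSurface:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        vals = np.asarray(tifffile.imread(path), dtype=float)
        return RasterSurface(vals, cell_size=cell_size, origin=origin, tag=tag)
    return read_ascii_grid(path, tag=tag)
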