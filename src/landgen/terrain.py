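"""Terrain indices and point-density surfaces derived from a DEM.

TRI follows the squared-difference (Riley) convention: the root of the sum
of squared elevation differences between a cell and its eight neighbors.
TPI is the cell elevation minus the mean of its eight neighbors.  Border
cells use whichever neighbors exist rather than padded elevations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import RasterSurface

_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_stack(values: np.ndarray) -> np.ndarray:
    """(8, nr, nc) stack of neighbor elevations, NaN where absent."""
    nr, nc = values.shape
    out = np.full((8, nr, nc), np.nan)
    for k, (dr, dc) in enumerate(_SHIFTS):
        src = values[max(0, -dr):nr - max(0, dr), max(0, -dc):nc - max(0, dc)]
        out[k, max(0, dr):nr - max(0, -dr), max(0, dc):nc - max(0, -dc)] = src
    return out


def _check_dem(dem: RasterSurface) -> None:
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    if dem.missing.all():
        raise ValueError("DEM is entirely missing")


def tri(dem: RasterSurface, variant: str = "riley") -> RasterSurface:
    """Terrain ruggedness index.

    ``riley``: sqrt(sum of squared differences to the 8 neighbors);
    ``mean_abs``: mean absolute difference (alternate convention).
    """
    _check_dem(dem)
    nb = _neighbor_stack(dem.values)
    diff = dem.values[None] - nb
    with np.errstate(invalid="ignore"):
        if variant == "riley":
            vals = np.sqrt(np.nansum(diff ** 2, axis=0))
        elif variant == "mean_abs":
            vals = np.nanmean(np.abs(diff), axis=0)
        else:
            raise ValueError(f"unknown TRI variant {variant!r}")
    vals[dem.missing | np.isnan(nb).all(axis=0)] = np.nan
    return dem.copy(values=vals, tag="tri")


def tpi(dem: RasterSurface) -> RasterSurface:
    """Topographic position index: elevation minus 8-neighbor mean.

    Positive on ridges, negative in valleys, ~0 on constant slope.
    """
    _check_dem(dem)
    nb = _neighbor_stack(dem.values)
    with np.errstate(invalid="ignore"):
        vals = dem.values - np.nanmean(nb, axis=0)
    vals[dem.missing | np.isnan(nb).all(axis=0)] = np.nan
    return dem.copy(values=vals, tag="tpi")


def point_density(points: np.ndarray, grid: RasterSurface, radius: float,
                  kernel: str = "quartic") -> RasterSurface:
    """Kernel density of point events on the template grid.

    Quartic kernel K(d) = (1 - (d/r)^2)^2 truncated at ``radius`` (the
    GIS-heatmap convention); cells beyond every point's radius are 0, so
    the surface reports "no fires here" rather than no-data.  Density is
    a plain kernel sum, hence linear in point multiplicity.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    vals = np.zeros(grid.shape)
    if len(points) == 0:
        return grid.copy(values=vals, tag="density")
    xs, ys = grid.cell_centers()
    for px, py in points:
        d2 = (xs - px) ** 2 + (ys - py) ** 2
        u = d2 / radius ** 2
        inside = u < 1.0
        if kernel == "quartic":
            vals[inside] += (1.0 - u[inside]) ** 2
        elif kernel == "epanechnikov":
            vals[inside] += 1.0 - u[inside]
        elif kernel == "uniform":
            vals[inside] += 1.0
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
    vals[grid.missing] = np.nan
    return grid.copy(values=vals, tag="density")


def read_points_csv(path, confidence_min: float | None = None) -> np.ndarray:
    """Point events from a CSV with columns x, y[, confidence]."""
    df = pd.read_csv(path)
    if confidence_min is not None and "confidence" in df.columns:
        df = df[df["confidence"].astype(float) > confidence_min]
    return df[["x", "y"]].to_numpy(dtype=float)
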