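"""Resistance-surface parameterization.

Continuous environmental rasters are rescaled to [0, 10] and pushed through
one of eight Monomolecular / Ricker transformation variants, then affinely
mapped so resistance spans [1, maximum].  Categorical rasters get per-class
resistance values with one reference class fixed at 1.  Composites are
cell-wise sums re-anchored to a minimum of 1.

Base curves (x in [0, 10], shape s > 0):

* Monomolecular  g(x) = 1 − exp(−x/s)      (monotone, saturating)
* Ricker         g(x) = x · exp(−x/s)      (humped, peak at x = s)

"Reverse" evaluates g at (10 − x); "Inverse" reflects the achieved curve
vertically (max g − g + min g).  "Distance" is the degenerate flat surface
(resistance 1 everywhere), the isolation-by-distance null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .raster import RasterSurface

FAMILIES = (
    "Monomolecular",
    "Reverse Monomolecular",
    "Inverse Monomolecular",
    "Inverse-Reverse Monomolecular",
    "Ricker",
    "Reverse Ricker",
    "Inverse Ricker",
    "Inverse-Reverse Ricker",
    "Distance",
)

SINGLE_MAX_BOUND = 5000.0
COMPOSITE_MAX_BOUND = 10000.0


@dataclass(frozen=True)
class TransformSpec:
    """Transformation family + shape + maximum defining a resistance surface."""

    family: str
    shape: float = 1.0
    maximum: float = 100.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "Distance":
            if not self.shape > 0:
                raise ValueError("shape must be positive")
            if not self.maximum > 1:
                raise ValueError("maximum must exceed 1")

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "shape": self.shape,
                           "maximum": self.maximum})

    @classmethod
    def from_json(cls, text: str) -> "TransformSpec":
        d = json.loads(text)
        return cls(d["family"], d.get("shape", 1.0), d.get("maximum", 100.0))


@dataclass(frozen=True)
class CategoricalAssignment:
    """Per-class resistance values; exactly one reference class fixed at 1."""

    values: dict
    bound: float = SINGLE_MAX_BOUND

    def __post_init__(self) -> None:
        vals = list(self.values.values())
        if sum(1 for v in vals if v == 1.0) < 1:
            raise ValueError("exactly one reference feature must be fixed at 1")
        if any(not 0 < v <= self.bound for v in vals):
            raise ValueError(f"resistance values must lie in (0, {self.bound}]")

    def to_json(self) -> str:
        return json.dumps({"values": {str(k): v for k, v in self.values.items()},
                           "bound": self.bound})


def rescale(surface: RasterSurface, lo: float = 0.0, hi: float = 10.0) -> RasterSurface:
    """Affine map of values onto [lo, hi]; missing preserved."""
    v = surface.values
    vmin, vmax = np.nanmin(v), np.nanmax(v)
    if not vmax > vmin:
        raise ValueError("constant surface: transformation unidentifiable")
    out = lo + (v - vmin) * (hi - lo) / (vmax - vmin)
    return surface.copy(values=out)


def _base_curve(x: np.ndarray, family: str, shape: float) -> np.ndarray:
    if "Reverse" in family:
        x = 10.0 - x
    if "Monomolecular" in family:
        g = 1.0 - np.exp(-x / shape)
    else:  # Ricker
        g = x * np.exp(-x / shape)
    if "Inverse" in family:
        g = np.nanmax(g) - g + np.nanmin(g)
    return g


def apply_transform(surface: RasterSurface, spec: TransformSpec) -> RasterSurface:
    """Transform a rescaled ([0, 10]) surface into resistances in [1, maximum]."""
    v = surface.values
    if np.nanmin(v) < -1e-9 or np.nanmax(v) > 10.0 + 1e-9:
        raise ValueError("apply_transform expects values rescaled to [0, 10]")
    if spec.family == "Distance":
        out = np.where(np.isnan(v), np.nan, 1.0)
        return surface.copy(values=out, tag="resistance")
    g = _base_curve(v, spec.family, spec.shape)
    gmin, gmax = np.nanmin(g), np.nanmax(g)
    if not gmax > gmin:  # flat achieved curve degenerates to the IBD null
        out = np.where(np.isnan(v), np.nan, 1.0)
    else:
        out = 1.0 + (g - gmin) * (spec.maximum - 1.0) / (gmax - gmin)
    return surface.copy(values=out, tag="resistance")


def apply_categorical(surface: RasterSurface, assignment: CategoricalAssignment) -> RasterSurface:
    """Label -> resistance lookup on a categorical raster."""
    v = surface.values
    labels = set(np.unique(v[~np.isnan(v)]).tolist())
    table = {float(k): float(val) for k, val in assignment.values.items()}
    uncovered = labels - set(table)
    if uncovered:
        raise ValueError(f"labels without assigned resistance: {sorted(uncovered)}")
    out = np.full(v.shape, np.nan)
    for lab, res in table.items():
        out[v == lab] = res
    return surface.copy(values=out, tag="resistance")


def combine(surfaces: list[RasterSurface]) -> RasterSurface:
    """Cell-wise sum of component resistances, re-anchored to minimum 1."""
    if not surfaces:
        raise ValueError("no surfaces to combine")
    base = surfaces[0]
    for s in surfaces[1:]:
        if s.shape != base.shape:
            raise ValueError("composite components must share the grid")
    total = np.sum([s.values for s in surfaces], axis=0)
    total = total - np.nanmin(total) + 1.0
    return base.copy(values=total, tag="resistance")


def percent_contribution(components: list[RasterSurface]) -> list[float]:
    """Share of each component in a composite: range of its transformed
    values relative to the total range (a flat "Distance" component
    contributes ~0)."""
    ranges = [float(np.nanmax(c.values) - np.nanmin(c.values)) for c in components]
    total = sum(ranges)
    if total == 0:
        return [100.0 / len(components)] * len(components)
    return [100.0 * r / total for r in ranges]
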