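"""Predictor-stack utilities: variable sets, point extraction, distance layers,
and standardization statistics shared between baseline and scenario stacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grid import GridSpec, PredictorStack, Raster

logger = logging.getLogger(__name__)

VARIABLE_SET_NAMES = ("HLCAm", "LCAm", "Cm")

# Default membership of the three nested model variable sets. The climate +
# topography core (bioclim layers, elevation, slope) is shared by all three;
# LCAm adds land cover and anthropogenic pressure; HLCAm adds habitat layers.
DEFAULT_VARIABLE_SETS: dict[str, list[str]] = {
    "Cm": ["bio15", "bio18", "bio19", "bio2", "bio3", "elevation", "slope"],
    "LCAm": [
        "bio15", "bio18", "bio19", "bio2", "bio3", "elevation", "slope",
        "landcover", "dist_road", "dist_river", "human_modification", "human_footprint",
    ],
    "HLCAm": [
        "bio15", "bio18", "bio19", "bio2", "bio3", "elevation", "slope",
        "landcover", "dist_road", "dist_river", "human_modification", "human_footprint",
        "ndvi", "tree_canopy", "forest_type",
    ],
}


@dataclass
class VariableSetSpec:
    """One of the three nested model variable sets (HLCAm ⊇ LCAm ⊇ Cm core)."""

    name: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name not in VARIABLE_SET_NAMES:
            raise ValueError(f"variable set name must be one of {VARIABLE_SET_NAMES}")
        if not self.members:
            self.members = list(DEFAULT_VARIABLE_SETS[self.name])

    def validate_against(self, stack: PredictorStack) -> None:
        missing = [m for m in self.members if m not in stack]
        if missing:
            raise KeyError(f"variable set {self.name}: layers missing from stack: {missing}")


def extract_at_points(
    stack: PredictorStack, x: np.ndarray, y: np.ndarray, names: list[str] | None = None
) -> pd.DataFrame:
    """Nearest-cell layer values at planar points.

    Points outside the extent or on no-data cells are excluded; the count of
    exclusions is logged and exposed via the frame's ``attrs["n_excluded"]``.
    Row index refers back to the input point order.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    names = names or stack.names
    inside = stack.grid.contains(x, y)
    row, col = stack.grid.rowcol(np.where(inside, x, stack.grid.x0), np.where(inside, y, stack.grid.y0))
    row = np.clip(row, 0, stack.grid.n_rows - 1)
    col = np.clip(col, 0, stack.grid.n_cols - 1)
    ok = inside & stack.mask[row, col]
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("extract_at_points: excluded %d points (outside extent or no-data)", n_excluded)
    data = {name: stack[name][row[ok], col[ok]] for name in names}
    out = pd.DataFrame(data, index=np.flatnonzero(ok))
    out.attrs["n_excluded"] = n_excluded
    return out


def distance_raster(features, grid: GridSpec, name: str = "distance") -> Raster:
    """Per-cell Euclidean distance (km) from cell center to the nearest feature.

    ``features`` is an iterable of shapely geometries (typically LineStrings).
    With no features, every cell gets the maximum-representable distance for
    the extent (the grid diagonal) and the raster is flagged degenerate.
    """
    xs, ys = grid.cell_centers()
    features = [f for f in features if f is not None and not f.is_empty]
    if not features:
        xmin, ymin, xmax, ymax = grid.extent_km
        sentinel = float(np.hypot(xmax - xmin, ymax - ymin))
        r = Raster(np.full(grid.shape, sentinel), grid, name=name)
        r.degenerate = True
        return r
    pts = shapely.points(xs.ravel(), ys.ravel())
    dist = np.full(pts.shape, np.inf)
    for feat in features:
        dist = np.minimum(dist, shapely.distance(pts, feat))
    r = Raster(dist.reshape(grid.shape), grid, name=name)
    r.degenerate = False
    return r


@dataclass
class Standardizer:
    """Z-score statistics for continuous layers, frozen on the baseline stack.

    The same means/stds are reused when projecting onto scenario stacks so a
    +2° shifted layer is seen by the model as shifted, not re-centred.
    """

    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)

    @classmethod
    def fit(cls, stack: PredictorStack, names: list[str] | None = None) -> "Standardizer":
        names = names or [n for n in stack.names if n not in stack.categorical]
        means, stds = {}, {}
        for n in names:
            if n in stack.categorical:
                continue
            v = stack[n][stack.mask]
            means[n] = float(v.mean())
            s = float(v.std())
            stds[n] = s if s > 0 else 1.0
        return cls(means, stds)

    def transform_layer(self, name: str, values: np.ndarray) -> np.ndarray:
        return (values - self.means[name]) / self.stds[name]

    def transform_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for n in out.columns:
            if n in self.means:
                out[n] = (out[n] - self.means[n]) / self.stds[n]
        return out
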