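"""Gridded raster containers.

Rasters live on a regular planar grid in kilometre units: row 0 is the
northern edge, columns increase eastward, and cell values are referenced to
cell centers. This keeps distance-based operations (spatial thinning,
pseudo-absence buffers, ESZ rings) exact without geodesy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely


class AlignmentError(ValueError):
    """Two rasters do not share a grid."""


@dataclass(frozen=True)
class GridSpec:
    """Georeference of a regular planar grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; row 0 is the northernmost row.
    cell_size_km : float
        Side length of a (square) cell in km.
    x0, y0 : float
        Coordinates of the grid's top-left *corner* (west edge, north edge).
    crs : str
        Free-form CRS tag; ``"synthetic-km"`` for generated landscapes,
        ``"lonlat"`` for geographic inputs.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 1.0
    x0: float = 0.0
    y0: float = None  # type: ignore[assignment]
    crs: str = "synthetic-km"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.y0 is None:
            object.__setattr__(self, "y0", self.n_rows * self.cell_size_km)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def extent_km(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x0,
            self.y0 - self.n_rows * self.cell_size_km,
            self.x0 + self.n_cols * self.cell_size_km,
            self.y0,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays of shape (n_rows, n_cols)."""
        cs = self.cell_size_km
        x = self.x0 + (np.arange(self.n_cols) + 0.5) * cs
        y = self.y0 - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(x, y)

    def rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) indices for planar coordinates."""
        cs = self.cell_size_km
        col = np.floor((np.asarray(x, float) - self.x0) / cs).astype(int)
        row = np.floor((self.y0 - np.asarray(y, float)) / cs).astype(int)
        return row, col

    def xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates for (row, col) indices."""
        cs = self.cell_size_km
        x = self.x0 + (np.asarray(col) + 0.5) * cs
        y = self.y0 - (np.asarray(row) + 0.5) * cs
        return x, y

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class Raster:
    """A single grid-aligned layer: values + validity mask + georeference."""

    values: np.ndarray
    grid: GridSpec
    mask: np.ndarray | None = None  # True where valid; None => all valid
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise AlignmentError(
                f"layer shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise AlignmentError("mask shape does not match grid")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def aligned_with(self, other: "Raster") -> bool:
        return self.grid == other.grid

    def require_aligned(self, other: "Raster") -> None:
        if not self.aligned_with(other):
            raise AlignmentError("rasters are not grid-aligned")

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.grid, self.mask.copy(), self.name)


@dataclass
class PredictorStack:
    """Named, grid-aligned predictor layers sharing one validity mask.

    ``categorical`` names the layers holding integer class codes (land cover,
    forest type); every other layer is treated as continuous.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    categorical: set[str] = field(default_factory=set)
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise AlignmentError(f"layer {name!r} does not match grid shape")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.layers:
            raise KeyError(f"no layer named {name!r}")
        return self.layers[name]

    def add(self, name: str, values: np.ndarray, categorical: bool = False) -> None:
        values = np.asarray(values)
        if values.shape != self.grid.shape:
            raise AlignmentError(f"layer {name!r} does not match grid shape")
        self.layers[name] = values
        if categorical:
            self.categorical.add(name)

    def raster(self, name: str) -> Raster:
        return Raster(self[name], self.grid, self.mask, name)

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing layers: {missing}")
        return PredictorStack(
            grid=self.grid,
            layers={n: self.layers[n] for n in names},
            categorical={n for n in names if n in self.categorical},
            mask=self.mask,
            meta=dict(self.meta),
        )

    def copy(self) -> "PredictorStack":
        return PredictorStack(
            grid=self.grid,
            layers={n: v.copy() for n, v in self.layers.items()},
            categorical=set(self.categorical),
            mask=self.mask.copy(),
            meta=dict(self.meta),
        )

    def valid_table(self, names: list[str] | None = None) -> np.ndarray:
        """Stack valid-cell values into an (n_valid, n_layers) matrix."""
        names = names or self.names
        return np.column_stack([self[n][self.mask] for n in names])


def polygon_cell_mask(grid: GridSpec, geometry) -> np.ndarray:
    """Boolean mask of cells whose *center* lies inside ``geometry``.

    Center-in-polygon is the standard unbiased zonal-statistics rule.
    """
    if geometry is None or geometry.is_empty:
        return np.zeros(grid.shape, dtype=bool)
    xs, ys = grid.cell_centers()
    return shapely.contains_xy(geometry, xs.ravel(), ys.ravel()).reshape(grid.shape)
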