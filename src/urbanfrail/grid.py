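"""Planar raster grids in a local projected (meter) frame.

The urban-quality method only needs Euclidean geometry, so coordinates are
planar meters throughout; any CRS identifier is carried as an opaque string
and never used for reprojection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

RasterKind = Literal["distance", "score", "index"]


@dataclass(frozen=True)
class GridSpec:
    """Regular raster grid: ``n_rows`` x ``n_cols`` square cells.

    The origin is the lower-left corner of cell (0, 0); cell centers sit at
    ``origin + (i + 0.5) * cell_size``. Row index increases with y.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 50.0
    n_rows: int = 100
    n_cols: int = 100
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.width,
            self.origin_y + self.height,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of x and y center coordinates."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) of the containing cell.

        Cell extents are half-open, [x0, x0 + cs) x [y0, y0 + cs), so a point
        on a shared edge belongs to the cell above/right of the edge; points
        on the outer top/right boundary of the grid are outside.
        """
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class RasterField:
    """A grid plus one value per cell.

    ``kind`` declares the semantics: ``distance`` (meters, >= 0), ``score``
    (proximity score in {1, 2, 3}) or ``index`` (sum of score layers).
    """

    grid: GridSpec
    values: np.ndarray
    kind: RasterKind = "distance"
    n_layers: int = field(default=1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("raster contains non-finite values")
        if self.kind == "distance":
            if np.any(v < 0):
                raise ValueError("distance raster has negative values")
        elif self.kind == "score":
            if not np.all(np.isin(v, (1, 2, 3))):
                raise ValueError("score raster values must be in {1, 2, 3}")
        elif self.kind == "index":
            lo, hi = self.n_layers, 3 * self.n_layers
            if np.any(v < lo) or np.any(v > hi) or np.any(v != np.round(v)):
                raise ValueError(
                    f"index raster must be integer-valued in [{lo}, {hi}]"
                )
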