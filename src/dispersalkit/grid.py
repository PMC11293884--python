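"""Planar raster grid with plain-text (ESRI ASCII) persistence.

All spatial data in this package live on a single square-celled grid in a
projected coordinate system with units of meters.  Arrays are stored with
row 0 at the *top* (maximum y), matching raster convention, and values are
attributed to cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class RasterGrid:
    """Geometry of a regular square-celled raster.

    Parameters
    ----------
    x0, y0
        Coordinates of the lower-left corner of the grid (meters).
    cell
        Cell size (meters).
    nrows, ncols
        Array shape.
    """

    x0: float
    y0: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def width_m(self) -> float:
        return self.ncols * self.cell

    @property
    def height_m(self) -> float:
        return self.nrows * self.cell

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate vectors of column / row cell centers."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell
        return xs, ys

    def index_of(self, x, y):
        """Row/col indices of the cells containing points (vectorized).

        Points outside the extent get index -1 in both row and col.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(np.int64)
        row = np.floor((self.y0 + self.height_m - y) / self.cell).astype(np.int64)
        # points exactly on the top/right edge belong to the edge cell
        col = np.where((x == self.x0 + self.width_m), self.ncols - 1, col)
        row = np.where((y == self.y0), self.nrows - 1, row)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        col = np.where(inside, col, -1)
        row = np.where(inside, row, -1)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, _ = self.index_of(x, y)
        return np.asarray(row) >= 0


def write_ascii_grid(path: str | Path, grid: RasterGrid, values: np.ndarray) -> None:
    """Write a single-band raster as an ESRI ASCII grid (text)."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"array shape {values.shape} != grid shape {grid.shape}")
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0}\n"
        f"cellsize {grid.cell}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[RasterGrid, np.ndarray]:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = RasterGrid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
    )
    values = values.reshape(grid.shape)
    return grid, values
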