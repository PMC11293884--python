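"""Seedable synthetic landscapes: land-cover patches, roads, and elevation.

The generator produces the raster inputs the rest of the pipeline consumes:
a single integer-coded land-cover raster (six classes plus background) and a
smooth elevation field, on a common square-celled grid.  Land-cover patches
are Poisson-placed discs; four-wheel-drive roads are random straight
transects one cell wide; elevation is a sum of low-frequency sinusoids
scaled to a configured relief.  Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariates import CLASS_CODES, CovariateStack, build_stack
from .grid import RasterGrid

__all__ = ["LandscapeConfig", "Landscape", "generate_landscape"]

#: order in which classes are rasterized; later classes overwrite earlier ones
CLASS_ORDER = ["forest", "shrub", "water", "hay_crop", "developed", "road4wd"]


@dataclass
class LandscapeConfig:
    """Configuration of a synthetic landscape.

    Parameters
    ----------
    extent_m
        Width/height of the square domain (meters); must be an integer
        multiple of ``cell_m``.
    cell_m
        Cell size, default 30 m.
    patch_density
        Expected patches per km^2 for each land-cover class; classes absent
        from the mapping get density 0.  For ``road4wd`` the density counts
        transects per 100 km^2 (roads are lines, not discs).
    patch_radius_m
        Nominal disc radius per class (a single float applies to all);
        realized radii are uniform in [0.5, 1.5] x nominal.
    elevation_relief_m
        Peak-to-trough amplitude of the elevation field.
    """

    extent_m: float
    cell_m: float = 30.0
    patch_density: dict[str, float] = field(default_factory=dict)
    patch_radius_m: float | dict[str, float] = 150.0
    elevation_relief_m: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_m <= 0:
            raise ValueError("cell_m must be positive")
        ncells = self.extent_m / self.cell_m
        if abs(ncells - round(ncells)) > 1e-9:
            raise ValueError("extent_m must be an integer multiple of cell_m")
        if round(ncells) < 3:
            raise ValueError("domain must be at least 3 x 3 cells")
        for cls, d in self.patch_density.items():
            if d < 0:
                raise ValueError(f"negative density for class {cls!r}")
            if cls not in CLASS_CODES:
                raise ValueError(f"unknown land-cover class {cls!r}")

    def radius_for(self, cls: str) -> float:
        if isinstance(self.patch_radius_m, dict):
            return float(self.patch_radius_m.get(cls, 150.0))
        return float(self.patch_radius_m)


@dataclass
class Landscape:
    """A generated landscape: raw rasters plus the derived covariate stack."""

    grid: RasterGrid
    class_raster: np.ndarray
    elevation: np.ndarray
    stack: CovariateStack
    n_patches: dict[str, int]


def _rasterize_discs(class_raster, grid, cx, cy, radius, code):
    """Paint many discs of one class: cells whose centers fall inside a
    disc get ``code``; a disc covering no cell center paints its center
    cell.  Vectorized over discs by looping over the (small) neighborhood
    of cell offsets instead of over the (many) discs.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    radius = np.asarray(radius, dtype=float)
    xs, ys = grid.cell_centers()
    rows, cols = grid.index_of(
        np.clip(cx, grid.x0, grid.x0 + grid.width_m - 1e-9),
        np.clip(cy, grid.y0 + 1e-9, grid.y0 + grid.height_m))
    half = int(np.ceil(radius.max() / grid.cell)) + 1
    painted = np.zeros(len(cx), dtype=bool)
    r2 = radius**2
    for dr in range(-half, half + 1):
        rr = rows + dr
        ok_r = (rr >= 0) & (rr < grid.nrows)
        if not ok_r.any():
            continue
        for dc in range(-half, half + 1):
            cc = cols + dc
            ok = ok_r & (cc >= 0) & (cc < grid.ncols)
            if not ok.any():
                continue
            idx = np.nonzero(ok)[0]
            dx = xs[cc[idx]] - cx[idx]
            dy = ys[rr[idx]] - cy[idx]
            sel = idx[dx * dx + dy * dy <= r2[idx]]
            class_raster[rows[sel] + dr, cols[sel] + dc] = code
            painted[sel] = True
    miss = ~painted
    class_raster[rows[miss], cols[miss]] = code


def _rasterize_line(class_raster, grid, x0, y0, angle, code):
    """Mark a 1-cell-wide straight transect through (x0, y0) at ``angle``."""
    diag = np.hypot(grid.width_m, grid.height_m)
    ts = np.arange(-diag, diag, grid.cell / 2)
    xs = x0 + ts * np.cos(angle)
    ys = y0 + ts * np.sin(angle)
    row, col = grid.index_of(xs, ys)
    ok = row >= 0
    class_raster[row[ok], col[ok]] = code


def _elevation_field(grid: RasterGrid, relief_m: float, rng: np.random.Generator) -> np.ndarray:
    """Sum of low-frequency sinusoids at ridge-and-basin wavelengths.

    Wavelengths are absolute (3-12 km) rather than extent-relative so that
    terrain ruggedness has comparable local variance on small and large
    domains.
    """
    xs, ys = grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    z = np.zeros(grid.shape)
    for k in range(10):
        wavelength = rng.uniform(2000.0, 12000.0)
        theta = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        amp = 1.0 / (k + 1)
        z += amp * np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / wavelength + phase)
    ptp = float(np.ptp(z))
    if relief_m > 0 and ptp > 0:
        z = (z - z.min()) / ptp * relief_m
    else:
        z = np.zeros(grid.shape)
    return z


def generate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Generate class/elevation rasters and the derived covariate stack."""
    n = int(round(cfg.extent_m / cfg.cell_m))
    grid = RasterGrid(x0=0.0, y0=0.0, cell=cfg.cell_m, nrows=n, ncols=n)
    rng = np.random.default_rng(cfg.seed)
    area_km2 = (cfg.extent_m / 1000.0) ** 2
    class_raster = np.zeros(grid.shape, dtype=np.int16)
    n_patches: dict[str, int] = {}
    for cls in CLASS_ORDER:
        density = cfg.patch_density.get(cls, 0.0)
        code = CLASS_CODES[cls]
        if density == 0:
            n_patches[cls] = 0
            continue
        if cls == "road4wd":
            count = max(int(rng.poisson(density * area_km2)), 1)
            for _ in range(count):
                x0 = rng.uniform(grid.x0, grid.x0 + grid.width_m)
                y0 = rng.uniform(grid.y0, grid.y0 + grid.height_m)
                _rasterize_line(class_raster, grid, x0, y0, rng.uniform(0, np.pi), code)
        else:
            count = max(int(rng.poisson(density * area_km2)), 1)
            nominal = cfg.radius_for(cls)
            cx = rng.uniform(grid.x0, grid.x0 + grid.width_m, size=count)
            cy = rng.uniform(grid.y0, grid.y0 + grid.height_m, size=count)
            radius = nominal * rng.uniform(0.5, 1.5, size=count)
            _rasterize_discs(class_raster, grid, cx, cy, radius, code)
        n_patches[cls] = count
    elevation = _elevation_field(grid, cfg.elevation_relief_m, rng)
    stack = build_stack(grid, class_raster, elevation)
    return Landscape(grid=grid, class_raster=class_raster, elevation=elevation,
                     stack=stack, n_patches=n_patches)
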