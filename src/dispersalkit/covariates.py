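"""Covariate layers on a common grid: distance-to, log transform, terrain
ruggedness, collinearity screening, and point extraction.

Distance-to layers are Euclidean center-to-center distances (meters) from
every cell to the nearest cell of the target land-cover class; they are
log-transformed as ``ln(d + offset)`` with a half-cell-width offset so the
transform is defined on-feature and remains scale-aware.  Layers are
z-scored with a stack-wide mean/SD so selection coefficients are comparable
across layers and sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import RasterGrid

__all__ = [
    "CovariateStack",
    "distance_to",
    "log_distance",
    "terrain_ruggedness",
    "build_stack",
    "screen_collinear",
    "extract_at",
]

#: Sentinel distance for a layer whose target class has no cells on the map.
DEGENERATE_SENTINEL = 1.0e7


def distance_to(class_raster: np.ndarray, class_codes, grid: RasterGrid) -> tuple[np.ndarray, bool]:
    """Distance (m) from each cell center to the nearest cell of any listed code.

    Returns ``(raster, degenerate)``.  A degenerate layer (no target cells)
    is filled with a large sentinel and flagged; downstream fits exclude it.
    """
    codes = np.atleast_1d(np.asarray(class_codes))
    target = np.isin(class_raster, codes)
    if not target.any():
        return np.full(class_raster.shape, DEGENERATE_SENTINEL), True
    # exact Euclidean distance transform over non-target cells
    dist = ndimage.distance_transform_edt(~target, sampling=grid.cell)
    return dist, False


def log_distance(raster: np.ndarray, offset_m: float = 15.0) -> np.ndarray:
    """``ln(d + offset_m)``; monotone in d, defined at d = 0."""
    raster = np.asarray(raster, dtype=float)
    if (raster < 0).any():
        raise ValueError("distance raster has negative values")
    return np.log(raster + offset_m)


def terrain_ruggedness(elevation: np.ndarray) -> np.ndarray:
    """Riley terrain ruggedness index.

    Per cell: square root of the summed squared elevation differences with
    the 8 neighboring cells; edge cells use the neighbors that exist.
    """
    z = np.asarray(elevation, dtype=float)
    ss = np.zeros_like(z)
    nr, nc = z.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(dr, 0), nr + min(dr, 0)
            q0, q1 = max(dc, 0), nc + min(dc, 0)
            diff = z[r0:r1, q0:q1] - z[r0 - dr:r1 - dr, q0 - dc:q1 - dc]
            ss[r0:r1, q0:q1] += diff**2
    return np.sqrt(ss)


@dataclass
class CovariateStack:
    """Named covariate rasters sharing one grid.

    ``standardization`` maps layer name -> (mean, sd) used for z-scoring;
    ``transform_log`` records which layers are stored log-transformed;
    ``flagged`` lists degenerate layers excluded from model fitting.
    """

    grid: RasterGrid
    layers: dict[str, np.ndarray]
    transform_log: set[str] = field(default_factory=set)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    flagged: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
        if not self.standardization:
            for name, arr in self.layers.items():
                sd = float(arr.std())
                self.standardization[name] = (float(arr.mean()), sd if sd > 0 else 1.0)

    @property
    def active_layers(self) -> list[str]:
        return [n for n in sorted(self.layers) if n not in self.flagged]


# default mapping of land-cover class name -> integer code in the class raster
CLASS_CODES = {
    "forest": 1,
    "shrub": 2,
    "water": 3,
    "hay_crop": 4,
    "developed": 5,
    "road4wd": 6,
}


def build_stack(
    grid: RasterGrid,
    class_raster: np.ndarray,
    elevation: np.ndarray,
    class_codes: dict[str, int] | None = None,
    log_offset_m: float = 15.0,
) -> CovariateStack:
    """Assemble the standard covariate stack from a class raster and elevation.

    Produces one log-distance layer per land-cover class (``dist_<class>``),
    plus ``elevation`` and ``tri``.
    """
    codes = dict(CLASS_CODES if class_codes is None else class_codes)
    layers: dict[str, np.ndarray] = {}
    transform_log: set[str] = set()
    flagged: set[str] = set()
    for name, code in codes.items():
        dist, degenerate = distance_to(class_raster, code, grid)
        lname = f"dist_{name}"
        if degenerate:
            layers[lname] = dist
            flagged.add(lname)
        else:
            layers[lname] = log_distance(dist, log_offset_m)
            transform_log.add(lname)
    layers["elevation"] = np.asarray(elevation, dtype=float)
    layers["tri"] = terrain_ruggedness(elevation)
    return CovariateStack(grid=grid, layers=layers, transform_log=transform_log, flagged=flagged)


def screen_collinear(stack: CovariateStack, sample_xy: np.ndarray, r_max: float = 0.60) -> list[str]:
    """Drop one layer of every pair with |Pearson r| > ``r_max``.

    Correlations are computed on layer values at ``sample_xy`` (n x 2 array
    of points).  While any offending pair remains, the member of the worst
    pair with the larger mean |r| against all remaining layers is dropped;
    ties break alphabetically (the later name is dropped).  Returns retained
    layer names (sorted).
    """
    sample_xy = np.asarray(sample_xy, dtype=float)
    if sample_xy.shape[0] < 30:
        raise ValueError("need at least 30 sample points for the correlation screen")
    names = list(stack.active_layers)
    if len(names) < 2:
        return names
    vals = extract_at(stack, sample_xy[:, 0], sample_xy[:, 1], names, standardized=False)
    keep = []
    for n in names:
        if np.std(vals[n]) == 0:
            warnings.warn(f"layer {n!r} is constant at sample points; dropped from screen")
        else:
            keep.append(n)
    names = keep
    while len(names) > 1:
        mat = np.corrcoef(np.vstack([vals[n] for n in names]))
        np.fill_diagonal(mat, 0.0)
        absr = np.abs(mat)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= r_max:
            break
        # drop the member with larger mean |r| against all remaining layers
        mean_i = absr[i].sum() / (len(names) - 1)
        mean_j = absr[j].sum() / (len(names) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j, key=lambda k: names[k])
        names.pop(drop)
    return sorted(names)


def extract_at(
    stack: CovariateStack,
    x,
    y,
    which_layers=None,
    standardized: bool = False,
) -> dict[str, np.ndarray]:
    """Nearest-cell layer values at points; off-extent points yield NaN.

    No interpolation: land-cover distance layers are piecewise and bilinear
    blending would blur the on-feature zero.
    """
    if which_layers is None:
        which_layers = stack.active_layers
    row, col = stack.grid.index_of(x, y)
    row = np.atleast_1d(row)
    col = np.atleast_1d(col)
    inside = row >= 0
    out: dict[str, np.ndarray] = {}
    for name in which_layers:
        arr = stack.layers[name]
        vals = np.full(row.shape, np.nan)
        vals[inside] = arr[row[inside], col[inside]]
        if standardized:
            mu, sd = stack.standardization[name]
            vals = (vals - mu) / sd
        out[name] = vals
    return out
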