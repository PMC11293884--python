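"""Build a synthetic landscape and inspect its covariate stack.

Generates a 9 x 9 km landscape of Poisson-placed land-cover patches, road
transects and sinusoidal terrain, derives the log distance-to layers plus
elevation and terrain ruggedness, runs the pairwise collinearity screen,
and writes one layer to a plain-text raster.
"""

import numpy as np

import os
import tempfile

from dispersalkit import LandscapeConfig, generate_landscape, screen_collinear, write_ascii_grid

cfg = LandscapeConfig(
    extent_m=9000.0,
    cell_m=30.0,
    patch_density={"forest": 0.6, "shrub": 0.8, "water": 0.12,
                   "hay_crop": 0.15, "developed": 0.12, "road4wd": 0.02},
    elevation_relief_m=600.0,
    seed=7,
)
land = generate_landscape(cfg)

print(f"grid: {land.grid.nrows} x {land.grid.ncols} cells of {land.grid.cell:.0f} m")
print("patches placed per class:", land.n_patches)
print("covariate layers:", ", ".join(sorted(land.stack.layers)))
print("log-transformed:", ", ".join(sorted(land.stack.transform_log)))

rng = np.random.default_rng(0)
pts = np.column_stack([rng.uniform(0, 9000, 2000), rng.uniform(0, 9000, 2000)])
kept = screen_collinear(land.stack, pts, r_max=0.60)
print("retained after |r| > .60 screen:", ", ".join(kept))
# dropped layers were collinear (r beyond .60) with a retained one at these
# 2,000 random sample points

out_path = os.path.join(tempfile.gettempdir(), "elevation.asc")
write_ascii_grid(out_path, land.grid, land.stack.layers["elevation"])
print(f"wrote elevation raster to {out_path} (ESRI ASCII grid)")
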