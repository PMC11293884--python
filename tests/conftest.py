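import numpy as np
import pandas as pd
import pytest

from dispersalkit.grid import RasterGrid
from dispersalkit.covariates import CovariateStack
from dispersalkit.landscape import LandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A 6 x 6 km landscape shared by fast tests."""
    cfg = LandscapeConfig(
        extent_m=6000.0,
        cell_m=30.0,
        patch_density={"forest": 1.0, "shrub": 1.2, "water": 0.3,
                       "hay_crop": 0.3, "developed": 0.3, "road4wd": 0.05},
        elevation_relief_m=400.0,
        seed=1234,
    )
    return generate_landscape(cfg)


@pytest.fixture()
def simple_grid():
    return RasterGrid(x0=0.0, y0=0.0, cell=30.0, nrows=40, ncols=40)


@pytest.fixture()
def noise_stack(simple_grid):
    """Stack of independent Gaussian-noise layers on a small grid."""
    rng = np.random.default_rng(7)
    layers = {f"n{i}": rng.normal(size=simple_grid.shape) for i in range(4)}
    return CovariateStack(grid=simple_grid, layers=layers)


def make_fixes(times_h, xy, t0="2022-01-01T00:00:00Z"):
    """Fix table from hour offsets and coordinate pairs."""
    t0 = pd.Timestamp(t0)
    return pd.DataFrame({
        "t": [t0 + pd.Timedelta(hours=float(h)) for h in times_h],
        "x": [float(p[0]) for p in xy],
        "y": [float(p[1]) for p in xy],
    })
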