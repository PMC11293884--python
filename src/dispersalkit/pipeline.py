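"""End-to-end conveniences tying the modules together.

Two workflows are provided:

* the *estimator path* — simulate a site's worth of animals on a shared
  landscape under known selection coefficients, fit each animal's
  step-selection model, and pool to site level; this is the workhorse of
  the recovery and power studies; and
* the *segmentation path* — simulate full dispersal trajectories through a
  scheduled sequence of behavioral states and recover the states from the
  daily net-squared-displacement series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .issa import (
    IssaFit,
    ModelSpec,
    fit_clogit,
    fit_tentative_kernel,
    generate_random_steps,
    attach_covariates,
    steps_from_burst,
)
from .landscape import Landscape, LandscapeConfig, generate_landscape
from .nsd import (
    SegmentationParams,
    StateSegment,
    classify_states,
    compute_nsd,
    estimate_natal_range,
)
from .pooling import pool
from .preprocess import Burst
from .simulate import FixScheduleConfig, Track, TrueModel, simulate_track

__all__ = [
    "site_landscape_config",
    "dispersal_landscape_config",
    "TRUE_BETA",
    "start_points",
    "simulate_site_animal",
    "fit_track",
    "simulate_site",
    "dispersal_schedule",
    "simulate_disperser",
    "segment_track",
    "daily_state_truth",
]

#: selection coefficients (standardized covariates) used by the recovery study
TRUE_BETA = {"dist_forest": -0.5, "tri": 0.25, "dist_developed": 0.3}

#: patch densities (patches per km^2; transect count per km^2 for roads)
# sparse classes use many small patches rather than few large ones (equal
# areal cover): a single home range then spans many independent patches, so
# per-animal information about the distance-to fields matches what the
# model-based standard errors assume
DEFAULT_DENSITIES = {
    "forest": 0.6,
    "shrub": 0.8,
    "water": 0.3,
    "hay_crop": 0.4,
    "developed": 0.5,
    "road4wd": 0.01,
}

DEFAULT_RADII = {
    "forest": 400.0,
    "shrub": 500.0,
    "water": 100.0,
    "hay_crop": 180.0,
    "developed": 100.0,
}


def site_landscape_config(seed: int, extent_m: float = 150000.0, cell_m: float = 120.0) -> LandscapeConfig:
    """Landscape for estimator studies (150 x 150 km, 120 m cells): wide
    enough that free-ranging simulated animals (root-mean-square wander
    ~20 km over 300 four-hour steps) essentially never meet the boundary."""
    return LandscapeConfig(
        extent_m=extent_m, cell_m=cell_m,
        patch_density=dict(DEFAULT_DENSITIES),
        patch_radius_m=dict(DEFAULT_RADII),
        elevation_relief_m=600.0, seed=seed,
    )


def dispersal_landscape_config(seed: int) -> LandscapeConfig:
    """Larger, coarser landscape (100 x 100 km, 120 m cells) leaving room
    for multi-week departures without boundary effects."""
    return LandscapeConfig(
        extent_m=100080.0, cell_m=120.0,
        patch_density=dict(DEFAULT_DENSITIES),
        patch_radius_m=dict(DEFAULT_RADII),
        elevation_relief_m=600.0, seed=seed,
    )


def start_points(land: Landscape, n_animals: int) -> list[tuple[float, float]]:
    """Staggered lattice of start locations in the landscape's central block.

    Starts are spread over the central 30% of the extent so that each
    animal samples a different neighborhood, while the remaining 35% margin
    on every side keeps free-ranging walks away from the boundary.
    """
    ncol = (n_animals + 1) // 2
    block_w = 0.3 * land.grid.width_m
    block_h = 0.3 * land.grid.height_m
    x_lo = land.grid.x0 + (land.grid.width_m - block_w) / 2
    y_lo = land.grid.y0 + (land.grid.height_m - block_h) / 2
    dx = block_w / ncol
    ys = y_lo + block_h * np.array([0.25, 0.75])
    points = []
    for r, y in enumerate(ys):
        # stagger alternate rows by half a column
        xs = x_lo + dx * (np.arange(ncol) + 0.25 + 0.5 * r)
        points.extend((float(x), float(y)) for x in xs)
    return points[:n_animals]


def simulate_site_animal(
    land: Landscape,
    beta: dict[str, float],
    n_strata: int = 300,
    seed: int | None = None,
    animal_id: str = "sim",
    start: tuple[float, float] | None = None,
    gamma_shape: float = 2.0,
    gamma_scale: float = 400.0,
    vm_kappa: float = 0.5,
    n_candidates: int = 200,
) -> Track:
    """One animal moving freely under ``beta`` — a draw from the
    step-selection model class itself, with no confinement.

    The track starts at ``start`` (default: domain center) and is long
    enough to yield ``n_strata`` strata at a 4-h fix rate.  The generative
    process is exactly the model the estimator fits: candidate endpoints
    from the movement kernels, chosen by habitat log-weights alone.  Any
    extra mechanism (e.g. home-range attraction) that the fitted model
    could only approximate would leak locality-dependent error into the
    habitat coefficients and spoil the calibration the validation studies
    certify; confined movement lives in the dispersal simulator instead.
    The generative side draws 200 candidate steps so the discrete choice
    closely approximates the continuous redistribution kernel the estimator
    targets (the analysis still matches each used step with 20 random
    steps).
    """
    if start is None:
        start = (land.grid.x0 + land.grid.width_m / 2,
                 land.grid.y0 + land.grid.height_m / 2)
    n_ticks = n_strata + 3
    days = n_ticks * 240.0 / (24 * 60)
    model = TrueModel(
        beta=dict(beta),
        gamma_shape=gamma_shape, gamma_scale=gamma_scale, vm_kappa=vm_kappa,
        state_schedule=[("established", days)],
        natal_center=start,
        attraction_per_m=0.0,
    )
    sched = FixScheduleConfig(nominal_interval_min=240.0)
    return simulate_track(land.stack, model, sched, n_candidates=n_candidates,
                          seed=seed, animal_id=animal_id)


def fit_track(
    track: Track,
    land: Landscape,
    habitat_terms: list[str],
    n_random: int = 20,
    seed: int | None = None,
    include_interactions: bool = False,
    state: str = "all",
    home_range_term: bool = False,
) -> IssaFit:
    """Tentative kernels -> matched random steps -> conditional logit fit.

    ``home_range_term`` adds a nuisance covariate ``home_excess`` — the
    end-point's distance (km) beyond the track's empirical home-range
    radius (0.9 quantile of fix distances from the fix centroid).  For
    home-ranging field animals, range fidelity is part of the movement
    process; leaving it out of the conditional logit attenuates the habitat
    coefficients even though it is roughly orthogonal to them
    (non-collapsibility of the logit).  Two caveats, both measured on
    simulated confined movement: the term only *approximates* true range
    fidelity, and the residual leaks locality-dependent error into the
    habitat coefficients (between-animal heterogeneity on the order of half
    a per-animal SE) that model-based and pooled SEs cannot see; and
    because it is constructed from the fitted track itself, its estimation
    error contributes further between-individual variance.  Treat pooled
    SEs from home-ranging animals as optimistic.
    """
    burst = Burst(track.animal_id, track.fixes[["t", "x", "y"]], 240.0)
    used = steps_from_burst(burst)
    kernel = fit_tentative_kernel(used["sl"].to_numpy(), used["ta"].to_numpy())
    steps = generate_random_steps(burst, kernel, n_random=n_random, seed=seed)
    steps = attach_covariates(steps, land.stack, habitat_terms)
    terms = list(habitat_terms)
    if home_range_term:
        cx = track.fixes["x"].mean()
        cy = track.fixes["y"].mean()
        r_home = np.quantile(np.hypot(track.fixes["x"] - cx, track.fixes["y"] - cy), 0.9)
        d_end = np.hypot(steps["x_end"] - cx, steps["y_end"] - cy)
        steps["home_excess"] = np.maximum(0.0, d_end - r_home) / 1000.0
        terms = terms + ["home_excess"]
    spec = ModelSpec(habitat_terms=terms,
                     include_interactions=include_interactions)
    return fit_clogit(steps, spec, animal_id=track.animal_id, state=state)


def simulate_site(
    land: Landscape,
    beta: dict[str, float],
    n_animals: int = 10,
    n_strata: int = 300,
    seed: int = 0,
    site: str = "site",
    habitat_terms: list[str] | None = None,
) -> tuple[list[IssaFit], pd.DataFrame]:
    """Simulate, fit and pool a site's worth of free-ranging animals."""
    if habitat_terms is None:
        habitat_terms = sorted(beta)
    rng = np.random.default_rng(seed)
    starts = start_points(land, n_animals)
    fits = []
    for i in range(n_animals):
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        track = simulate_site_animal(land, beta, n_strata=n_strata, seed=int(s1),
                                     animal_id=f"{site}-{i:02d}", start=starts[i])
        fits.append(fit_track(track, land, habitat_terms, seed=int(s2)))
    pooled = pool(fits, site=site)
    return fits, pooled


def dispersal_schedule() -> list[tuple[str, float]]:
    """Canonical scheduled dispersal: residency, an exploratory sally with
    return, renewed residency, departure, then a transient home range held
    until collar drop (< 6 months)."""
    return [
        ("natal", 45.0),
        ("exploratory", 24.0),
        ("natal", 10.0),
        ("departure", 16.0),
        ("transient_home_range", 90.0),
    ]


def simulate_disperser(
    land: Landscape,
    seed: int,
    animal_id: str = "disperser",
    beta: dict[str, float] | None = None,
    schedule: list[tuple[str, float]] | None = None,
) -> Track:
    """Simulate a full dispersal trajectory over the scheduled states."""
    center = (land.grid.x0 + land.grid.width_m / 2, land.grid.y0 + land.grid.height_m / 2)
    model = TrueModel(
        beta=beta if beta is not None else {"dist_forest": -0.3, "tri": 0.2},
        gamma_shape=2.0, gamma_scale=300.0, vm_kappa=0.5,
        state_schedule=schedule or dispersal_schedule(),
        natal_center=center,
        natal_radius_m=2000.0,
        drift_strength=0.6,
        attraction_per_m=0.01,
    )
    sched = FixScheduleConfig(nominal_interval_min=240.0)
    return simulate_track(land.stack, model, sched, n_candidates=20, seed=seed,
                          animal_id=animal_id)


def segment_track(
    track: Track,
    params: SegmentationParams | None = None,
) -> tuple[list[StateSegment], tuple[float, float], float]:
    """Estimate the natal range and classify dispersal states for a track."""
    params = params or SegmentationParams()
    fixes = track.fixes[["t", "x", "y"]]
    origin, radius = estimate_natal_range(fixes, params, animal_id=track.animal_id)
    series = compute_nsd(fixes, origin, animal_id=track.animal_id)
    segments = classify_states(series, radius, params)
    return segments, origin, radius


def daily_state_truth(track: Track, days: pd.DatetimeIndex) -> np.ndarray:
    """Scheduled (ground-truth) state for each calendar day, taken at local noon."""
    out = np.empty(len(days), dtype=object)
    for i, day in enumerate(days):
        t = day + pd.Timedelta(hours=12)
        label = track.true_segments[-1][0]
        for state, t0, t1 in track.true_segments:
            if t0 <= t < t1:
                label = state
                break
        out[i] = label
    return out
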