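"""Validation experiments: the package checking itself against ground truth.

Every function here recomputes a validation quantity from scratch — running
the simulator, the estimator or the segmentation on freshly generated data —
and returns plain numbers.  The test suite asserts on them; the acceptance
script reports them.  Oracles (grid-search likelihood maximization,
brute-force distance/ruggedness) are implemented here independently of the
production code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import distance_to, terrain_ruggedness
from .grid import RasterGrid
from .issa import fit_clogit
from .landscape import generate_landscape
from .pipeline import (
    TRUE_BETA,
    daily_state_truth,
    dispersal_landscape_config,
    segment_track,
    simulate_disperser,
    simulate_site,
    site_landscape_config,
)
from .pooling import compare_sites, pool
from .preprocess import Burst, detect_clusters
from .simulate import Track, inject_cluster

__all__ = [
    "clogit_grid_oracle",
    "grid_search_clogit",
    "recovery_experiment",
    "two_site_power",
    "segmentation_recovery",
    "cluster_exactness",
    "pooling_closed_form",
    "distance_tri_oracle",
    "null_calibration",
    "permutation_null",
]


# ---------------------------------------------------------------------------
# conditional-likelihood oracle


def _toy_clogit_instance(rng, n_strata, n_cand, p, beta_true):
    """A small matched-stratum dataset drawn from the choice model itself."""
    X = rng.normal(size=(n_strata, n_cand, p))
    eta = X @ np.asarray(beta_true)
    w = np.exp(eta - eta.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    used = np.array([rng.choice(n_cand, p=w[s]) for s in range(n_strata)])
    y = np.zeros((n_strata, n_cand), dtype=int)
    y[np.arange(n_strata), used] = 1
    strata = np.repeat(np.arange(n_strata), n_cand)
    return X.reshape(-1, p), strata, y.ravel()


def _cond_loglik(X, strata, y, betas):
    """Conditional log-likelihood at many beta vectors (betas: m x p)."""
    n_cand = np.bincount(strata)[0]
    n_strata = strata.max() + 1
    eta = (X @ betas.T).reshape(n_strata, n_cand, -1)
    used = y.reshape(n_strata, n_cand).argmax(axis=1)
    mx = eta.max(axis=1)
    lse = np.log(np.exp(eta - mx[:, None, :]).sum(axis=1)) + mx
    return (eta[np.arange(n_strata), used, :] - lse).sum(axis=0)


def grid_search_clogit(X, strata, y, lo=-4.0, hi=4.0, coarse_step=1e-3, final_step=1e-5):
    """Exhaustive staged grid search of the conditional likelihood.

    One coefficient: a full grid at ``coarse_step``, then shrinking
    exhaustive grids around the incumbent down to ``final_step``.  Two
    coefficients: the coarse stage uses a 0.05 grid (the full 1e-3 product
    grid is redundant for a concave likelihood), then the same shrinking
    refinement per axis down to ``final_step``.
    """
    p = X.shape[1]
    if p == 1:
        grid = np.arange(lo, hi + coarse_step, coarse_step)[:, None]
        best = grid[np.argmax(_cond_loglik(X, strata, y, grid))]
        step = coarse_step
    elif p == 2:
        step = 0.05
        g = np.arange(lo, hi + step, step)
        bb = np.array(np.meshgrid(g, g)).reshape(2, -1).T
        best = bb[np.argmax(_cond_loglik(X, strata, y, bb))]
    else:
        raise ValueError("oracle supports at most 2 coefficients")
    while step > final_step:
        step /= 10
        axes = [np.arange(b - 15 * step, b + 15 * step + step / 2, step) for b in best]
        if p == 1:
            bb = axes[0][:, None]
        else:
            bb = np.array(np.meshgrid(*axes)).reshape(p, -1).T
        best = bb[np.argmax(_cond_loglik(X, strata, y, bb))]
    return np.asarray(best, dtype=float)


def clogit_grid_oracle(seed: int = 0, n_instances: int = 8) -> float:
    """Max |beta_fit - beta_grid| over toy instances (<= 2 coef, <= 10 strata)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        p = 1 if i % 2 == 0 else 2
        n_strata = int(rng.integers(5, 11))
        n_cand = int(rng.integers(2, 5))
        beta_true = rng.uniform(-1, 1, size=p)
        X, strata, y = _toy_clogit_instance(rng, n_strata, n_cand, p, beta_true)
        fit = fit_clogit(X, strata_ids=strata, y=y, names=[f"b{j}" for j in range(p)],
                         min_strata=1)
        if not fit.converged:
            continue  # separation on a tiny draw: the oracle diverges too
        ref = grid_search_clogit(X, strata, y)
        est = np.array([fit.beta[f"b{j}"] for j in range(p)])
        if np.max(np.abs(est)) > 3.5:
            continue  # optimum outside the oracle grid; skip rather than clip
        worst = max(worst, float(np.max(np.abs(est - ref))))
    return worst


# ---------------------------------------------------------------------------
# parameter recovery and power


def recovery_experiment(
    seed: int = 0,
    n_reps: int = 100,
    n_animals: int = 10,
    n_strata: int = 300,
    beta_true: dict[str, float] | None = None,
) -> dict:
    """Pooled-estimate recovery of known selection coefficients.

    Returns, per term: the replicate-mean pooled estimate, the mean pooled
    SE, the truth, and CI coverage; plus overall coverage across terms.
    """
    beta_true = dict(TRUE_BETA if beta_true is None else beta_true)
    terms = sorted(beta_true)
    rng = np.random.default_rng(seed)
    est = {t: [] for t in terms}
    ses = {t: [] for t in terms}
    cover = {t: 0 for t in terms}
    for _ in range(n_reps):
        land_seed, site_seed = rng.integers(0, 2**31 - 1, size=2)
        land = generate_landscape(site_landscape_config(int(land_seed)))
        _, pooled = simulate_site(land, beta_true, n_animals=n_animals,
                                  n_strata=n_strata, seed=int(site_seed))
        pooled = pooled.set_index("term")
        for t in terms:
            row = pooled.loc[t]
            est[t].append(row["beta_bar"])
            ses[t].append(row["se_bar"])
            if row["ci_low"] <= beta_true[t] <= row["ci_high"]:
                cover[t] += 1
    out = {"terms": {}, "n_reps": n_reps}
    total_cover = 0
    for t in terms:
        out["terms"][t] = {
            "truth": beta_true[t],
            "mean_estimate": float(np.mean(est[t])),
            "mean_pooled_se": float(np.mean(ses[t])),
            "bias": float(np.mean(est[t]) - beta_true[t]),
            "coverage_pct": 100.0 * cover[t] / n_reps,
        }
        total_cover += cover[t]
    out["overall_coverage_pct"] = 100.0 * total_cover / (n_reps * len(terms))
    out["max_abs_bias_over_2se"] = max(
        abs(v["bias"]) / (2 * v["mean_pooled_se"]) for v in out["terms"].values())
    return out


def two_site_power(
    seed: int = 0,
    n_reps: int = 50,
    n_animals: int = 10,
    n_strata: int = 300,
    effect: float = 0.4,
) -> dict:
    """Two-site contrast: an anthropogenic-avoidance effect present at site A
    (beta_dist_developed = +effect, i.e. selection for larger distances)
    and absent at site B, all else equal.

    Success on a replicate: site A significant and site B non-significant
    for dist_developed in the side-by-side comparison.
    """
    base = {"dist_forest": -0.5, "tri": 0.25}
    beta_a = dict(base, dist_developed=effect)
    beta_b = dict(base, dist_developed=0.0)
    terms = sorted(beta_a)
    rng = np.random.default_rng(seed)
    n_success = 0
    for _ in range(n_reps):
        land_seed, sa, sb = rng.integers(0, 2**31 - 1, size=3)
        land = generate_landscape(site_landscape_config(int(land_seed)))
        _, pooled_a = simulate_site(land, beta_a, n_animals, n_strata, seed=int(sa),
                                    site="A", habitat_terms=terms)
        _, pooled_b = simulate_site(land, beta_b, n_animals, n_strata, seed=int(sb),
                                    site="B", habitat_terms=terms)
        cmp = compare_sites(pooled_a, pooled_b, "A", "B").set_index("term")
        row = cmp.loc["dist_developed"]
        if bool(row["significant_A"]) and not bool(row["significant_B"]):
            n_success += 1
    return {"n_reps": n_reps, "success_rate_pct": 100.0 * n_success / n_reps}


# ---------------------------------------------------------------------------
# segmentation recovery


def segmentation_recovery(seed: int = 0, n_animals: int = 20) -> dict:
    """State recovery on scheduled-state simulated dispersers.

    Per-day accuracy is the fraction of classified days whose label matches
    the scheduled state; change-point error is the mean absolute offset (in
    days) between each true transition and the nearest predicted one.
    """
    rng = np.random.default_rng(seed)
    land = generate_landscape(dispersal_landscape_config(int(rng.integers(0, 2**31 - 1))))
    day_hits = 0
    day_total = 0
    cp_errors = []
    n_flagged = 0
    for i in range(n_animals):
        track = simulate_disperser(land, seed=int(rng.integers(0, 2**31 - 1)),
                                   animal_id=f"d{i:02d}")
        try:
            segments, origin, radius = segment_track(track)
        except Exception:
            n_flagged += 1
            continue
        # per-day comparison
        days = pd.DatetimeIndex(
            pd.date_range(segments[0].t_start, segments[-1].t_end, freq="D"))
        truth = daily_state_truth(track, days)
        pred = np.empty(len(days), dtype=object)
        for seg in segments:
            sel = (days >= seg.t_start) & (days <= seg.t_end)
            pred[sel] = seg.state
        ok = pred == truth
        day_hits += int(ok.sum())
        day_total += len(days)
        # change points
        t0 = track.true_segments[0][1]
        true_cps = [(t1 - t0) / pd.Timedelta(days=1)
                    for _, _, t1 in track.true_segments[:-1]]
        pred_cps = [(seg.t_start - t0) / pd.Timedelta(days=1) for seg in segments[1:]]
        for cp in true_cps:
            if pred_cps:
                cp_errors.append(min(abs(cp - p) for p in pred_cps))
            else:
                cp_errors.append((track.true_segments[-1][2] - t0) / pd.Timedelta(days=1))
    return {
        "n_animals": n_animals,
        "n_flagged": n_flagged,
        "per_day_accuracy_pct": 100.0 * day_hits / max(day_total, 1),
        "mean_change_point_error_days": float(np.mean(cp_errors)) if cp_errors else float("inf"),
    }


# ---------------------------------------------------------------------------
# cluster detection exactness


def _wandering_track(seed: int = 0, n: int = 60) -> Track:
    """Wide-ranging synthetic fixes (1 km steps, 4-h interval): no clusters."""
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp("2021-06-01T00:00:00Z")
    steps = rng.normal(0, 1000.0, size=(n, 2)) + np.array([800.0, 0.0])
    xy = np.cumsum(steps, axis=0)
    fixes = pd.DataFrame({
        "t": [t0 + pd.Timedelta(hours=4 * i) for i in range(n)],
        "x": xy[:, 0], "y": xy[:, 1], "true_state": "departure",
    })
    return Track(animal_id="wander", fixes=fixes)


def cluster_exactness(seed: int = 0) -> dict:
    """Detected cluster counts on constructed fixtures with k in {0, 1, 3}."""
    out = {}
    # k = 0: wide-ranging track only
    tr0 = _wandering_track(seed)
    b0 = Burst("wander", tr0.fixes[["t", "x", "y"]], 240.0)
    out["k0_detected"] = len(detect_clusters(b0))
    # k = 1: a single injected 4-fix / 24 h cluster; radius 70 m keeps the
    # cluster diameter under the 150 m buffer, so detection is geometric
    tr1 = inject_cluster(_wandering_track(seed), center=(50000.0, 50000.0),
                         radius_m=70.0, n_fixes=4, duration_h=24.0, seed=seed)
    b1 = Burst("one", tr1.fixes[["t", "x", "y"]].sort_values("t"), 240.0)
    out["k1_detected"] = len(detect_clusters(b1))
    # below minimum fix count: 3 fixes never form a cluster
    tr1b = inject_cluster(_wandering_track(seed), center=(50000.0, 50000.0),
                          radius_m=70.0, n_fixes=3, duration_h=24.0, seed=seed)
    b1b = Burst("below", tr1b.fixes[["t", "x", "y"]].sort_values("t"), 240.0)
    out["below_min_detected"] = len(detect_clusters(b1b))
    # k = 3: three well-separated injected clusters
    tr3 = _wandering_track(seed)
    for j, cx in enumerate((30000.0, 60000.0, 90000.0)):
        tr3 = inject_cluster(tr3, center=(cx, cx), radius_m=70.0, n_fixes=5,
                             duration_h=20.0, seed=seed + j,
                             t_start=tr3.fixes["t"].iloc[-1] + pd.Timedelta(hours=30))
    b3 = Burst("three", tr3.fixes[["t", "x", "y"]].sort_values("t"), 240.0)
    out["k3_detected"] = len(detect_clusters(b3))
    return out


# ---------------------------------------------------------------------------
# pooling closed forms


def pooling_closed_form() -> dict:
    """Inverse-variance pooling on hand-checkable inputs."""
    from .issa import IssaFit

    def mk(i, beta, se):
        return IssaFit(animal_id=f"a{i}", state="s", beta={"z": beta}, se={"z": se},
                       vcov=np.array([[se**2]]), names=["z"], loglik=0.0,
                       n_strata=100, converged=True)

    p = pool([mk(0, 1.0, 1.0), mk(1, 3.0, 1.0)]).set_index("term")
    equal = pool([mk(0, 0.2, 0.5), mk(1, 0.8, 0.5), mk(2, 1.1, 0.5)]).set_index("term")
    return {
        "beta_bar_1_3": float(p.loc["z", "beta_bar"]),
        "se_bar_1_3": float(p.loc["z", "se_bar"]),
        "equal_se_pool_minus_mean": float(equal.loc["z", "beta_bar"] - np.mean([0.2, 0.8, 1.1])),
    }


# ---------------------------------------------------------------------------
# raster oracles


def distance_tri_oracle(seed: int = 0, n: int = 50, cell: float = 30.0) -> dict:
    """Brute-force checks of the distance and ruggedness rasters."""
    rng = np.random.default_rng(seed)
    grid = RasterGrid(x0=0.0, y0=0.0, cell=cell, nrows=n, ncols=n)
    classes = (rng.uniform(size=(n, n)) < 0.02).astype(int)  # sparse targets
    if not classes.any():
        classes[n // 2, n // 2] = 1
    dist, flagged = distance_to(classes, 1, grid)
    # O(n^2) nearest-target oracle
    rows, cols = np.indices((n, n))
    trows, tcols = np.nonzero(classes)
    d2 = (rows[..., None] - trows) ** 2 + (cols[..., None] - tcols) ** 2
    brute = np.sqrt(d2.min(axis=-1)) * cell
    max_d_err = float(np.abs(dist - brute).max())

    elev = rng.normal(0, 100.0, size=(20, 20))
    tri = terrain_ruggedness(elev)
    brute_tri = np.zeros_like(elev)
    for r in range(20):
        for c in range(20):
            ss = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 20 and 0 <= cc < 20:
                        ss += (elev[r, c] - elev[rr, cc]) ** 2
            brute_tri[r, c] = np.sqrt(ss)
    max_tri_err = float(np.abs(tri - brute_tri).max())
    return {"max_distance_error_m": max_d_err, "max_tri_error_m": max_tri_err,
            "degenerate_flagged": bool(flagged)}


# ---------------------------------------------------------------------------
# null safety


def null_calibration(seed: int = 0, n_reps: int = 200, n_strata: int = 100,
                     n_cand: int = 21, p: int = 2, alpha: float = 0.05) -> dict:
    """Type-I error of per-term Wald tests under the no-selection null.

    Strata are drawn from the matched-choice model with beta = 0 (the used
    step uniform among candidates); the per-term rejection rate at
    ``alpha`` should sit inside its binomial 99% interval.
    """
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(1 - alpha / 2)
    rejections = np.zeros(p, dtype=int)
    n_fits = 0
    for _ in range(n_reps):
        X, strata, y = _toy_clogit_instance(rng, n_strata, n_cand, p, np.zeros(p))
        fit = fit_clogit(X, strata_ids=strata, y=y,
                         names=[f"b{j}" for j in range(p)], min_strata=1)
        if not fit.converged:
            continue
        n_fits += 1
        for j in range(p):
            if abs(fit.beta[f"b{j}"] / fit.se[f"b{j}"]) > z:
                rejections[j] += 1
    lo = int(stats.binom.ppf(0.005, n_fits, alpha))
    hi = int(stats.binom.ppf(0.995, n_fits, alpha))
    return {
        "n_fits": n_fits,
        "rates_pct": [100.0 * r / n_fits for r in rejections],
        "binom99_lo_pct": 100.0 * lo / n_fits,
        "binom99_hi_pct": 100.0 * hi / n_fits,
        "all_within": bool(np.all((rejections >= lo) & (rejections <= hi))),
    }


def permutation_null(seed: int = 0, n_shuffles: int = 200, n_strata: int = 150,
                     n_cand: int = 21, p: int = 2) -> dict:
    """Shuffling used-labels within strata centers coefficients on zero."""
    rng = np.random.default_rng(seed)
    X, strata, y = _toy_clogit_instance(rng, n_strata, n_cand, p,
                                        np.array([0.5, -0.3][:p]))
    betas = []
    for _ in range(n_shuffles):
        y2 = y.reshape(n_strata, n_cand).copy()
        for s in range(n_strata):
            y2[s] = y2[s][rng.permutation(n_cand)]
        fit = fit_clogit(X, strata_ids=strata, y=y2.ravel(),
                         names=[f"b{j}" for j in range(p)], min_strata=1)
        if fit.converged:
            betas.append([fit.beta[f"b{j}"] for j in range(p)])
    betas = np.asarray(betas)
    return {
        "n_fits": int(len(betas)),
        "mean_beta": [float(m) for m in betas.mean(axis=0)],
        "max_abs_mean_beta": float(np.abs(betas.mean(axis=0)).max()),
        "mean_se_of_mean": float(betas.std(axis=0).mean() / np.sqrt(len(betas))),
    }
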