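"""Integrated step-selection analysis (iSSA).

Each observed ("used") step is matched with random ("available") steps
drawn from *tentative* movement kernels — a gamma distribution for step
length and a zero-centered von Mises for turning angle — fitted to the
animal's used steps.  Habitat covariates at step endpoints (and start-point
anthropogenic covariates interacting with movement characteristics) enter a
conditional logistic model whose matched-set likelihood is maximized per
individual.  The fitted movement coefficients refine the tentative kernels
(the "integrated" step of iSSA), and coefficient contrasts give the log
relative selection strength (log-RSS) between habitat profiles.

The conditional likelihood for stratum *s* with linear predictors
``eta_j = x_j . beta`` over its 1 used + K available steps is
``eta_used - log sum_j exp(eta_j)``; it is maximized by Newton iterations
on the analytic gradient and observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .covariates import CovariateStack, extract_at
from .preprocess import Burst

__all__ = [
    "MovementKernel",
    "ModelSpec",
    "IssaFit",
    "fit_tentative_kernel",
    "generate_random_steps",
    "attach_covariates",
    "build_design",
    "fit_clogit",
    "update_kernel",
    "log_rss",
    "steps_from_burst",
]

#: anthropogenic covariate layers (candidates for movement interactions)
ANTHROPOGENIC = ("dist_developed", "dist_hay_crop", "dist_road4wd")

#: GPS precision floor (m); zero step lengths are replaced by half of it
GPS_PRECISION_FLOOR_M = 5.0

MIN_STRATA = 30


@dataclass
class MovementKernel:
    gamma_shape: float
    gamma_scale: float  # meters
    vm_kappa: float
    vm_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be positive")
        if self.vm_kappa < 0:
            raise ValueError("vm_kappa must be non-negative")


@dataclass
class ModelSpec:
    """Terms of the global step-selection model.

    ``movement_terms`` default to the iSSA-standard transforms sl, log(sl)
    and cos(ta); interactions pair each movement term in
    ``interaction_movement`` with the start-point value of each
    anthropogenic covariate present among the habitat terms.
    """

    habitat_terms: list[str]
    movement_terms: tuple[str, ...] = ("sl", "log_sl", "cos_ta")
    interaction_movement: tuple[str, ...] = ("log_sl", "cos_ta")
    anthropogenic: tuple[str, ...] = ANTHROPOGENIC
    include_interactions: bool = True

    def columns(self) -> list[str]:
        cols = list(self.habitat_terms) + list(self.movement_terms)
        if self.include_interactions:
            for a in self.anthropogenic:
                if a in self.habitat_terms:
                    for m in self.interaction_movement:
                        cols.append(f"{m}:{a}_start")
        return cols


@dataclass
class IssaFit:
    animal_id: str
    state: str
    beta: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray
    names: list[str]
    loglik: float
    n_strata: int
    converged: bool
    dropped: list[str] = field(default_factory=list)


def fit_tentative_kernel(sl: np.ndarray, ta: np.ndarray) -> MovementKernel:
    """Fit the tentative movement kernels to used steps.

    Gamma (shape, scale) by maximum likelihood on step lengths (zeros
    replaced by half the GPS precision floor so the support is positive);
    von Mises concentration by maximum likelihood on turning angles with
    the mean direction fixed at zero.
    """
    sl = np.asarray(sl, dtype=float)
    sl = sl[np.isfinite(sl)]
    if len(sl) == 0 or np.all(sl == 0):
        raise ValueError("no usable (non-zero) step lengths")
    if len(sl) < 30:
        warnings.warn(f"only {len(sl)} used steps for kernel fitting")
    sl = np.where(sl == 0, GPS_PRECISION_FLOOR_M / 2.0, sl)
    shape, _, scale = stats.gamma.fit(sl, floc=0)
    ta = np.asarray(ta, dtype=float)
    ta = ta[np.isfinite(ta)]
    kappa = _vm_kappa_mle(ta) if len(ta) else 0.0
    return MovementKernel(gamma_shape=float(shape), gamma_scale=float(scale),
                          vm_kappa=float(kappa))


def _vm_kappa_mle(ta: np.ndarray) -> float:
    """MLE of the von Mises concentration with mu fixed at 0.

    Solves A(kappa) = I1(kappa)/I0(kappa) = mean(cos(ta)).
    """
    r = float(np.mean(np.cos(ta)))
    if r <= 0:
        return 0.0
    if r >= 1 - 1e-12:
        return 1e6

    def f(k):
        return special.i1e(k) / special.i0e(k) - r

    return float(optimize.brentq(f, 1e-9, 1e6))


def steps_from_burst(burst: Burst) -> pd.DataFrame:
    """Used steps (with turning angles) from a burst.

    A step runs fix i -> fix i+1; its turning angle needs the incoming
    bearing (fix i-1 -> i), so the burst's first step carries no ta and is
    not used to form a stratum.
    """
    f = burst.fixes
    x = f["x"].to_numpy(dtype=float)
    y = f["y"].to_numpy(dtype=float)
    t = f["t"].to_numpy()
    dx = np.diff(x)
    dy = np.diff(y)
    bearing = np.arctan2(dy, dx)
    sl = np.hypot(dx, dy)
    ta = np.full(len(sl), np.nan)
    dtheta = np.diff(bearing)
    ta[1:] = (dtheta + np.pi) % (2 * np.pi) - np.pi
    return pd.DataFrame({
        "t_start": t[:-1], "t_end": t[1:],
        "x_start": x[:-1], "y_start": y[:-1],
        "x_end": x[1:], "y_end": y[1:],
        "bearing_in": np.concatenate([[np.nan], bearing[:-1]]),
        "sl": sl, "ta": ta,
    })


def generate_random_steps(
    burst: Burst,
    kernel: MovementKernel,
    n_random: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Matched strata of 1 used + ``n_random`` available steps per fix.

    Available steps share the used step's start point and start time; their
    lengths are gamma draws and their turning angles von Mises draws
    relative to the incoming bearing, with endpoints by planar dead
    reckoning.  The first step of a burst (undefined turning angle) forms
    no stratum.  Returns a long step table with columns
    stratum_id / case / sl / ta / geometry.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if len(burst.fixes) < 3:
        raise ValueError("burst must have at least 3 fixes")
    if rng is None:
        rng = np.random.default_rng(seed)
    used = steps_from_burst(burst)
    used = used[np.isfinite(used["ta"])].reset_index(drop=True)
    n = len(used)
    if n == 0:
        return pd.DataFrame()
    sl_r = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, size=(n, n_random))
    if kernel.vm_kappa > 0:
        ta_r = rng.vonmises(kernel.vm_mu, kernel.vm_kappa, size=(n, n_random))
    else:
        ta_r = rng.uniform(-np.pi, np.pi, size=(n, n_random))
    bearing_in = used["bearing_in"].to_numpy()[:, None]
    head = bearing_in + ta_r
    x0 = used["x_start"].to_numpy()[:, None]
    y0 = used["y_start"].to_numpy()[:, None]
    ex = x0 + sl_r * np.cos(head)
    ey = y0 + sl_r * np.sin(head)

    S = n_random + 1
    rows = {
        "stratum_id": np.repeat(np.arange(n), S),
        "case": np.tile(np.array([1] + [0] * n_random), n),
        "t_start": np.repeat(used["t_start"].to_numpy(), S),
        "x_start": np.repeat(used["x_start"].to_numpy(), S),
        "y_start": np.repeat(used["y_start"].to_numpy(), S),
        "x_end": np.column_stack([used["x_end"], ex]).ravel(),
        "y_end": np.column_stack([used["y_end"], ey]).ravel(),
        "sl": np.column_stack([used["sl"], sl_r]).ravel(),
        "ta": np.column_stack([used["ta"], ta_r]).ravel(),
    }
    return pd.DataFrame(rows)


def attach_covariates(
    steps: pd.DataFrame,
    stack: CovariateStack,
    habitat_terms: list[str],
    anthropogenic: tuple[str, ...] = ANTHROPOGENIC,
    standardized: bool = True,
) -> pd.DataFrame:
    """Add end-point habitat values and start-point anthropogenic values.

    Strata with any missing (off-raster) endpoint value are dropped whole,
    so every remaining stratum stays balanced.
    """
    if steps.empty:
        return steps
    out = steps.copy()
    end_vals = extract_at(stack, steps["x_end"].to_numpy(), steps["y_end"].to_numpy(),
                          habitat_terms, standardized=standardized)
    for name, v in end_vals.items():
        out[name] = v
    start_names = [a for a in anthropogenic if a in stack.layers and a not in stack.flagged]
    if start_names:
        start_vals = extract_at(stack, steps["x_start"].to_numpy(), steps["y_start"].to_numpy(),
                                start_names, standardized=standardized)
        for name, v in start_vals.items():
            out[f"{name}_start"] = v
    value_cols = [c for c in out.columns if c not in
                  ("stratum_id", "case", "t_start")]
    bad = out[value_cols].isna().any(axis=1)
    if bad.any():
        bad_strata = out.loc[bad, "stratum_id"].unique()
        out = out[~out["stratum_id"].isin(bad_strata)]
    return out.reset_index(drop=True)


def build_design(steps: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design matrix, stratum ids and used indicator for the clogit."""
    df = steps
    cols = []
    names = spec.columns()
    sl = df["sl"].to_numpy(dtype=float)
    sl = np.where(sl <= 0, GPS_PRECISION_FLOOR_M / 2.0, sl)
    derived = {
        "sl": sl,
        "log_sl": np.log(sl),
        "cos_ta": np.cos(df["ta"].to_numpy(dtype=float)),
    }
    for name in names:
        if name in derived:
            cols.append(derived[name])
        elif ":" in name:
            m, a = name.split(":")
            cols.append(derived[m] * df[a].to_numpy(dtype=float))
        else:
            cols.append(df[name].to_numpy(dtype=float))
    X = np.column_stack(cols)
    return X, df["stratum_id"].to_numpy(), df["case"].to_numpy(), names


def _group_starts(strata_ids: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(strata_ids) != 0) + 1
    return np.concatenate([[0], change])


def fit_clogit(
    steps_or_X,
    spec: ModelSpec | None = None,
    *,
    animal_id: str = "animal",
    state: str = "all",
    strata_ids: np.ndarray | None = None,
    y: np.ndarray | None = None,
    names: list[str] | None = None,
    max_iter: int = 60,
    gtol: float = 1e-6,
    min_strata: int = MIN_STRATA,
) -> IssaFit:
    """Maximize the conditional (matched-set) logistic likelihood.

    Accepts either a step table plus a :class:`ModelSpec`, or an explicit
    design matrix with ``strata_ids`` / ``y`` / ``names``.  Columns with no
    within-stratum contrast are dropped with a warning.  Newton iterations
    on the analytic gradient and observed information, with step halving;
    convergence when the gradient infinity-norm falls below ``gtol``.
    Complete separation (diverging coefficients) is flagged non-converged
    with infinite standard errors.
    """
    if isinstance(steps_or_X, pd.DataFrame):
        if spec is None:
            raise ValueError("a ModelSpec is required with a step table")
        X, strata_ids, y, names = build_design(steps_or_X, spec)
    else:
        X = np.asarray(steps_or_X, dtype=float)
        if strata_ids is None or y is None:
            raise ValueError("strata_ids and y are required with a design matrix")
        names = list(names) if names else [f"x{i}" for i in range(X.shape[1])]
    order = np.argsort(strata_ids, kind="stable")
    X = X[order]
    strata_ids = np.asarray(strata_ids)[order]
    y = np.asarray(y)[order]
    starts = _group_starts(strata_ids)
    n_strata = len(starts)
    if n_strata < min_strata:
        warnings.warn(f"{animal_id}/{state}: only {n_strata} strata (minimum {min_strata})")
    sizes = np.diff(np.concatenate([starts, [len(strata_ids)]]))
    rep = np.repeat(np.arange(n_strata), sizes)

    # drop columns with no within-stratum contrast (incl. constant columns)
    group_mean = np.zeros((n_strata, X.shape[1]))
    np.add.at(group_mean, rep, X)
    group_mean /= sizes[:, None]
    centered = X - group_mean[rep]
    contrast = np.abs(centered).max(axis=0)
    dropped = [names[k] for k in range(X.shape[1]) if contrast[k] < 1e-10]
    if dropped:
        warnings.warn(f"{animal_id}/{state}: dropped no-contrast columns {dropped}")
        keep = [k for k in range(X.shape[1]) if contrast[k] >= 1e-10]
        X = X[:, keep]
        names = [names[k] for k in keep]
    p = X.shape[1]

    used_idx = np.flatnonzero(y == 1)
    if len(used_idx) != n_strata:
        raise ValueError("each stratum must contain exactly one used step")

    # complete-separation check: a covariate that perfectly ranks the used
    # step first (or last) in every stratum pushes its coefficient to
    # infinity; the Newton gradient decays below tolerance at a finite
    # value, so detect the ranking directly
    separated = False
    if p:
        masked = X.copy()
        masked[used_idx] = -np.inf
        avail_max = np.maximum.reduceat(masked, starts, axis=0)
        masked = X.copy()
        masked[used_idx] = np.inf
        avail_min = np.minimum.reduceat(masked, starts, axis=0)
        u = X[used_idx]
        for k in range(p):
            hi = (u[:, k] >= avail_max[:, k] - 1e-12).all() and \
                 (u[:, k] > avail_max[:, k] + 1e-12).any()
            lo_ = (u[:, k] <= avail_min[:, k] + 1e-12).all() and \
                  (u[:, k] < avail_min[:, k] - 1e-12).any()
            if hi or lo_:
                separated = True
                warnings.warn(f"{animal_id}/{state}: complete separation on "
                              f"{names[k]!r}; fit flagged non-converged")

    def loglik_grad_hess(beta):
        eta = X @ beta
        gmax = np.maximum.reduceat(eta, starts)
        ee = np.exp(eta - gmax[rep])
        denom = np.add.reduceat(ee, starts)
        w = ee / denom[rep]
        ll = float(np.sum(eta[used_idx] - (np.log(denom) + gmax)))
        M = np.zeros((n_strata, p))
        np.add.at(M, rep, w[:, None] * X)
        grad = X[used_idx].sum(axis=0) - M.sum(axis=0)
        H = np.einsum("ip,i,iq->pq", X, w, X) - M.T @ M  # observed information
        return ll, grad, H

    beta = np.zeros(p)
    ll, grad, H = loglik_grad_hess(beta)
    converged = False
    singular = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        # step halving
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll2, g2, H2 = loglik_grad_hess(cand)
            if ll2 >= ll - 1e-12:
                beta, ll, grad, H = cand, ll2, g2, H2
                break
            t /= 2
        else:
            break
        if np.max(np.abs(beta)) > 50:
            break
    if np.max(np.abs(beta)) > 50 or not np.all(np.isfinite(beta)) or separated:
        converged = False
    if converged and not singular:
        try:
            vcov = np.linalg.inv(H)
            se = np.sqrt(np.diag(vcov))
            if not np.all(np.isfinite(se)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            converged = False
            vcov = np.full((p, p), np.inf)
            se = np.full(p, np.inf)
    else:
        vcov = np.full((p, p), np.inf)
        se = np.full(p, np.inf)
    return IssaFit(
        animal_id=animal_id, state=state,
        beta=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        vcov=vcov, names=list(names), loglik=ll,
        n_strata=n_strata, converged=bool(converged), dropped=dropped,
    )


def update_kernel(tentative: MovementKernel, fit: IssaFit) -> MovementKernel:
    """Refine the tentative kernels with the fitted movement coefficients.

    shape' = shape + beta_log_sl; 1/scale' = 1/scale - beta_sl;
    kappa' = kappa + beta_cos_ta.  An update leaving the valid parameter
    domain raises.
    """
    b_log_sl = fit.beta.get("log_sl", 0.0)
    b_sl = fit.beta.get("sl", 0.0)
    b_cos_ta = fit.beta.get("cos_ta", 0.0)
    shape = tentative.gamma_shape + b_log_sl
    inv_scale = 1.0 / tentative.gamma_scale - b_sl
    kappa = tentative.vm_kappa + b_cos_ta
    if shape <= 0 or inv_scale <= 0:
        raise ValueError(
            f"invalid kernel update: shape'={shape:.4g}, 1/scale'={inv_scale:.4g}")
    return MovementKernel(gamma_shape=shape, gamma_scale=1.0 / inv_scale,
                          vm_kappa=max(kappa, 0.0))


def log_rss(fit: IssaFit, x1: dict[str, float], x2: dict[str, float],
            ci_level: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Log relative selection strength between habitat profiles x1 and x2.

    Returns ``(value, se, (ci_low, ci_high))`` where value = beta.(x1 - x2)
    and the CI is delta-method normal-theory at ``ci_level``.
    """
    missing = [k for k in x1 if k not in fit.beta] + [k for k in x2 if k not in fit.beta]
    if missing:
        raise KeyError(f"terms not in the fit: {sorted(set(missing))}")
    d = np.zeros(len(fit.names))
    for i, name in enumerate(fit.names):
        d[i] = x1.get(name, 0.0) - x2.get(name, 0.0)
    val = float(np.dot([fit.beta[n] for n in fit.names], d))
    var = float(d @ fit.vcov @ d)
    se = np.sqrt(var) if var >= 0 else float("inf")
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return val, se, (val - z * se, val + z * se)
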