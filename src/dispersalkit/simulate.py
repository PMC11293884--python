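"""Ground-truthed trajectory simulation from a known step-selection model.

Tracks are simulated as a discrete-choice biased random walk: at each fix
interval a set of candidate steps is drawn from gamma (step length) and von
Mises (turning angle) kernels, and one candidate is selected with
probability proportional to ``exp(beta . z(end) + state term)``, where ``z``
are standardized covariate values at the candidate endpoint.  Behavioral
states follow a fixed schedule so that ground-truth change points are exact;
home-ranging states add an attraction penalty beyond a radius of the state
center, and travelling states add an outward drift away from the natal
center (an exploratory state drifts out for its first half and homes back
for its second).  The fix schedule supports timestamp jitter and missed
fixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .covariates import CovariateStack

__all__ = [
    "TrueModel",
    "FixScheduleConfig",
    "Track",
    "simulate_track",
    "inject_cluster",
    "write_track",
    "read_track",
]

HOME_STATES = {"natal", "transient_home_range", "established"}
TRAVEL_STATES = {"exploratory", "departure"}


@dataclass
class TrueModel:
    """Generative step-selection model with known parameters.

    ``beta`` maps covariate layer names to selection coefficients on
    standardized covariates.  ``state_schedule`` is an ordered list of
    ``(state, duration_days)`` pairs; states are drawn from
    {natal, exploratory, departure, transient_home_range, established}.
    """

    beta: dict[str, float]
    gamma_shape: float = 2.0
    gamma_scale: float = 400.0  # meters
    vm_kappa: float = 0.5
    state_schedule: list[tuple[str, float]] = field(default_factory=lambda: [("established", 30.0)])
    natal_center: tuple[float, float] = (0.0, 0.0)
    natal_radius_m: float = 2000.0
    drift_strength: float = 3.0          # log-weight per mean-step of outward progress
    attraction_per_m: float = 0.01       # log-weight penalty per meter beyond the radius

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma kernel parameters must be positive")
        if self.vm_kappa < 0:
            raise ValueError("vm_kappa must be non-negative")
        for state, days in self.state_schedule:
            if days <= 0:
                raise ValueError("state durations must be positive")
            if state not in HOME_STATES | TRAVEL_STATES:
                raise ValueError(f"unknown state {state!r}")


@dataclass
class FixScheduleConfig:
    nominal_interval_min: float = 240.0
    jitter_sd_min: float = 0.0
    p_missed: float = 0.0
    t0: str = "2020-01-01T00:00:00Z"

    def __post_init__(self) -> None:
        if not (0 <= self.p_missed < 1):
            raise ValueError("p_missed must be in [0, 1)")
        if self.jitter_sd_min < 0:
            raise ValueError("jitter_sd_min must be non-negative")
        if self.nominal_interval_min <= 0:
            raise ValueError("nominal_interval_min must be positive")


@dataclass(eq=False)
class Track:
    """A simulated (or observed) trajectory for one animal.

    ``fixes`` has columns t (UTC timestamps), x, y and, for synthetic
    tracks, true_state.  ``true_segments`` carries the scheduled state
    intervals, the ground truth for segmentation tests.
    """

    animal_id: str
    fixes: pd.DataFrame
    true_segments: list[tuple[str, pd.Timestamp, pd.Timestamp]] = field(default_factory=list)
    n_truncated: int = 0


def _scheduled_state(schedule, elapsed_days):
    acc = 0.0
    for state, days in schedule:
        if elapsed_days < acc + days:
            return state, (elapsed_days - acc) / days
        acc += days
    return schedule[-1][0], 1.0


def simulate_track(
    stack: CovariateStack,
    model: TrueModel,
    sched: FixScheduleConfig,
    n_candidates: int = 20,
    seed: int | None = None,
    animal_id: str = "sim",
    max_retries: int = 20,
) -> Track:
    """Simulate one trajectory over the scheduled states.

    At every fix interval ``n_candidates`` candidate steps are drawn from
    the movement kernels and one is chosen with probability proportional to
    ``exp(beta . z)`` plus the state-dependent attraction/drift term.
    Candidates falling off the raster are redrawn up to ``max_retries``
    rounds; on exhaustion the offending candidates are truncated at the
    boundary and counted in ``Track.n_truncated``.
    """
    grid = stack.grid
    if not bool(grid.contains(*model.natal_center)):
        raise ValueError("natal_center lies outside the raster extent")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    beta_names = [k for k in model.beta if k in stack.layers and k not in stack.flagged]
    betavec = np.array([model.beta[k] for k in beta_names])
    std_layers = []
    for k in beta_names:
        mu, sd = stack.standardization[k]
        std_layers.append((stack.layers[k] - mu) / sd)

    total_days = sum(d for _, d in model.state_schedule)
    n_ticks = int(total_days * 24 * 60 / sched.nominal_interval_min)
    t0 = pd.Timestamp(sched.t0)
    mean_step = model.gamma_shape * model.gamma_scale
    eps = grid.cell * 1e-3

    pos = np.array(model.natal_center, dtype=float)
    bearing = rng.uniform(0, 2 * np.pi)
    home_center = np.array(model.natal_center, dtype=float)
    prev_state = None
    n_truncated = 0

    times, xs_out, ys_out, states_out = [], [], [], []

    for k in range(n_ticks):
        elapsed_days = k * sched.nominal_interval_min / (24 * 60)
        state, frac = _scheduled_state(model.state_schedule, elapsed_days)
        if state != prev_state:
            if state in ("transient_home_range", "established"):
                home_center = pos.copy()
            prev_state = state

        # candidate steps
        sl = rng.gamma(model.gamma_shape, model.gamma_scale, size=n_candidates)
        if model.vm_kappa > 0:
            ta = rng.vonmises(0.0, model.vm_kappa, size=n_candidates)
        else:
            ta = rng.uniform(-np.pi, np.pi, size=n_candidates)
        head = bearing + ta
        ex = pos[0] + sl * np.cos(head)
        ey = pos[1] + sl * np.sin(head)
        for _ in range(max_retries):
            out = ~grid.contains(ex, ey)
            if not out.any():
                break
            m = int(out.sum())
            sl2 = rng.gamma(model.gamma_shape, model.gamma_scale, size=m)
            ta2 = (rng.vonmises(0.0, model.vm_kappa, size=m) if model.vm_kappa > 0
                   else rng.uniform(-np.pi, np.pi, size=m))
            head2 = bearing + ta2
            ex[out] = pos[0] + sl2 * np.cos(head2)
            ey[out] = pos[1] + sl2 * np.sin(head2)
            head[out] = head2
        out = ~grid.contains(ex, ey)
        if out.any():
            n_truncated += int(out.sum())
            ex[out] = np.clip(ex[out], grid.x0 + eps, grid.x0 + grid.width_m - eps)
            ey[out] = np.clip(ey[out], grid.y0 + eps, grid.y0 + grid.height_m - eps)

        # selection weights
        row, col = grid.index_of(ex, ey)
        logw = np.zeros(n_candidates)
        for b, arr in zip(betavec, std_layers):
            logw += b * arr[row, col]
        if state == "natal":
            center, mode = np.array(model.natal_center), "attract"
        elif state in ("transient_home_range", "established"):
            center, mode = home_center, "attract"
        elif state == "exploratory":
            center = np.array(model.natal_center)
            if frac < 0.5:
                mode = "drift_out"
            else:
                # homing leg: drift back at the same rate as the outbound
                # leg until inside the natal radius, then hold
                d_now = float(np.hypot(*(pos - center)))
                mode = "drift_in" if d_now > model.natal_radius_m else "attract"
        else:  # departure
            center, mode = np.array(model.natal_center), "drift_out"
        d_cand = np.hypot(ex - center[0], ey - center[1])
        if mode == "attract":
            logw -= model.attraction_per_m * np.maximum(0.0, d_cand - model.natal_radius_m)
        else:
            d_cur = float(np.hypot(*(pos - center)))
            sign = 1.0 if mode == "drift_out" else -1.0
            logw += sign * model.drift_strength * (d_cand - d_cur) / mean_step
        logw -= logw.max()
        w = np.exp(logw)
        choice = rng.choice(n_candidates, p=w / w.sum())

        pos = np.array([ex[choice], ey[choice]])
        bearing = head[choice]

        t = t0 + pd.Timedelta(minutes=k * sched.nominal_interval_min)
        if sched.jitter_sd_min > 0:
            t = t + pd.Timedelta(minutes=float(rng.normal(0, sched.jitter_sd_min)))
        if rng.uniform() >= sched.p_missed:
            times.append(t)
            xs_out.append(pos[0])
            ys_out.append(pos[1])
            states_out.append(state)

    fixes = pd.DataFrame({
        "t": pd.to_datetime(times, utc=True),
        "x": xs_out,
        "y": ys_out,
        "true_state": states_out,
    })
    segments = []
    acc = 0.0
    for state, days in model.state_schedule:
        segments.append((state,
                         t0 + pd.Timedelta(days=acc),
                         t0 + pd.Timedelta(days=acc + days)))
        acc += days
    return Track(animal_id=animal_id, fixes=fixes, true_segments=segments,
                 n_truncated=n_truncated)


def inject_cluster(
    track: Track,
    center: tuple[float, float],
    radius_m: float,
    n_fixes: int,
    duration_h: float,
    grid=None,
    t_start: pd.Timestamp | None = None,
    seed: int | None = None,
) -> Track:
    """Insert a stationary run of fixes (a synthetic kill-site cluster).

    Fixes are confined within ``radius_m`` of ``center`` and span
    ``duration_h``; the original track is left untouched.  ``grid``, when
    given, validates that the center lies on the raster.
    """
    if n_fixes < 1:
        raise ValueError("n_fixes must be >= 1")
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    if grid is not None and not bool(grid.contains(*center)):
        raise ValueError("cluster center lies outside the raster extent")
    rng = np.random.default_rng(seed)
    if t_start is None:
        t_start = track.fixes["t"].iloc[-1] + pd.Timedelta(hours=1)
    if n_fixes == 1:
        ts = [pd.Timestamp(t_start)]
    else:
        spacing = duration_h / (n_fixes - 1)
        ts = [pd.Timestamp(t_start) + pd.Timedelta(hours=i * spacing) for i in range(n_fixes)]
    r = radius_m * np.sqrt(rng.uniform(size=n_fixes))
    th = rng.uniform(0, 2 * np.pi, size=n_fixes)
    new = pd.DataFrame({
        "t": pd.to_datetime(ts, utc=True),
        "x": center[0] + r * np.cos(th),
        "y": center[1] + r * np.sin(th),
        "true_state": "kill_site",
    })
    fixes = (
        pd.concat([track.fixes, new], ignore_index=True)
        .sort_values("t", kind="stable")
        .reset_index(drop=True)
    )
    return replace(track, fixes=fixes)


def write_track(path, track: Track) -> None:
    df = track.fixes.copy()
    df.insert(0, "animal_id", track.animal_id)
    df["t"] = df["t"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    df.to_csv(path, index=False)


def read_track(path) -> Track:
    df = pd.read_csv(path)
    df["t"] = pd.to_datetime(df["t"], utc=True)
    animal_id = str(df["animal_id"].iloc[0]) if len(df) else "unknown"
    return Track(animal_id=animal_id, fixes=df.drop(columns=["animal_id"]))
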