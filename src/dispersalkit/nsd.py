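"""Net-squared-displacement (NSD) dispersal-state segmentation.

NSD — the squared straight-line distance from a natal-range origin, taken at
one representative fix per day — has a characteristic temporal shape for
each dispersal behavior: residency is a low plateau, an exploratory sally
rises and falls back, a departure rises without returning, and home-range
establishment away from the natal range is a high plateau.  The original
shape definitions are visual; this module makes them operational with
explicit, configurable thresholds:

* a day is *in* the natal range when NSD <= return_threshold x radius^2,
  where the radius is a quantile of daily displacements during the initial
  residency window;
* an excursion of at least ``away_min_days`` that later re-enters is
  *exploratory*; one that never re-enters is a *departure* from its first
  day beyond threshold;
* within post-departure data, a maximal window whose NSD coefficient of
  variation stays below ``plateau_cv_max`` (21-day sliding window) is a
  *transient home range* if it spans under six months (183 days) and
  *established* otherwise.

Ambiguous days resolve by the precedence natal > plateau > travel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NsdSeries",
    "StateSegment",
    "SegmentationParams",
    "NatalRangeError",
    "compute_nsd",
    "estimate_natal_range",
    "classify_states",
    "summarize_states",
    "segments_to_frame",
]

SIX_MONTHS_DAYS = 183


class NatalRangeError(ValueError):
    """No natal residency plateau could be established for the animal."""


@dataclass
class NsdSeries:
    animal_id: str
    origin: tuple[float, float]
    days: pd.DatetimeIndex        # normalized calendar days with data
    nsd_km2: np.ndarray           # squared displacement from origin, km^2
    x: np.ndarray                 # coordinates of the chosen daily fix
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class StateSegment:
    animal_id: str
    state: str
    t_start: pd.Timestamp   # first day of the segment (inclusive)
    t_end: pd.Timestamp     # last day of the segment (inclusive)
    duration_days: int = 0
    path_km: float = float("nan")
    displacement_km: float = float("nan")


@dataclass
class SegmentationParams:
    natal_residency_min_days: int = 30
    natal_radius_quantile: float = 0.95
    return_threshold: float = 1.0       # multiple of radius^2
    away_min_days: int = 7
    plateau_cv_max: float = 0.15
    plateau_window_days: int = 21
    plateau_min_days: int = 7
    transient_max_days: int = SIX_MONTHS_DAYS

    def __post_init__(self) -> None:
        for name in ("natal_residency_min_days", "natal_radius_quantile", "return_threshold",
                     "away_min_days", "plateau_cv_max", "plateau_window_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _daily_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """One representative fix per calendar day: the fix nearest local noon."""
    df = fixes.copy()
    day = df["t"].dt.normalize()
    noon = day + pd.Timedelta(hours=12)
    df["_day"] = day
    df["_offnoon"] = (df["t"] - noon).abs()
    idx = df.groupby("_day")["_offnoon"].idxmin()
    out = df.loc[idx].sort_values("_day")
    return out[["_day", "t", "x", "y"]].rename(columns={"_day": "day"}).reset_index(drop=True)


def compute_nsd(fixes: pd.DataFrame, origin: tuple[float, float],
                animal_id: str = "animal") -> NsdSeries:
    """Daily NSD from ``origin`` (km^2), one fix per day nearest local noon.

    Days without fixes are simply absent — nothing is interpolated.
    """
    if len(fixes) == 0:
        raise ValueError("no fixes")
    daily = _daily_fixes(fixes.sort_values("t"))
    dx = (daily["x"].to_numpy() - origin[0]) / 1000.0
    dy = (daily["y"].to_numpy() - origin[1]) / 1000.0
    return NsdSeries(
        animal_id=animal_id,
        origin=(float(origin[0]), float(origin[1])),
        days=pd.DatetimeIndex(daily["day"]),
        nsd_km2=dx**2 + dy**2,
        x=daily["x"].to_numpy(),
        y=daily["y"].to_numpy(),
    )


def estimate_natal_range(
    fixes: pd.DataFrame,
    params: SegmentationParams | None = None,
    animal_id: str = "animal",
) -> tuple[tuple[float, float], float]:
    """Estimate the natal-range origin and radius from the initial residency.

    The origin is the centroid of fixes in the initial residency window
    (the first ``natal_residency_min_days`` days, extended day by day while
    subsequent daily fixes stay within the current radius); the radius is
    the ``natal_radius_quantile`` of daily distances from the origin within
    that window.  Residency requires the window to look like a plateau
    rather than a drift: the net displacement between the window's first
    and last daily fix must not exceed the quantile radius.  Animals that
    fail this are raised as :class:`NatalRangeError` and excluded
    downstream, mirroring the exclusion of collared animals that never
    display home-ranging behavior around the capture site.
    """
    params = params or SegmentationParams()
    daily = _daily_fixes(fixes.sort_values("t"))
    if len(daily) == 0:
        raise NatalRangeError(f"{animal_id}: no fixes")
    t0 = daily["day"].iloc[0]
    window = daily[daily["day"] < t0 + pd.Timedelta(days=params.natal_residency_min_days)]
    if (daily["day"].iloc[-1] - t0).days + 1 < params.natal_residency_min_days:
        raise NatalRangeError(
            f"{animal_id}: fewer than {params.natal_residency_min_days} days of data")

    def _fit(win: pd.DataFrame) -> tuple[np.ndarray, float]:
        cx, cy = win["x"].mean(), win["y"].mean()
        d = np.hypot(win["x"] - cx, win["y"] - cy)
        return np.array([cx, cy]), float(np.quantile(d, params.natal_radius_quantile))

    origin, radius = _fit(window)
    # plateau criterion: no systematic drift across the window, measured as
    # the distance between the centroids of its first and second halves
    # (robust to day-to-day wander, large under monotone drift)
    half = len(window) // 2
    c1 = window.iloc[:half][["x", "y"]].mean()
    c2 = window.iloc[half:][["x", "y"]].mean()
    net = float(np.hypot(c2["x"] - c1["x"], c2["y"] - c1["y"]))
    if net > radius:
        raise NatalRangeError(f"{animal_id}: no residency plateau in the initial window "
                              f"(half-window centroid shift {net:.0f} m > radius {radius:.0f} m)")
    # extend the window while subsequent daily fixes remain inside the range
    n0 = len(window)
    xs = daily["x"].to_numpy(dtype=float)
    ys = daily["y"].to_numpy(dtype=float)
    n_ext = n0
    while n_ext < len(daily) and np.hypot(
            xs[n_ext] - origin[0], ys[n_ext] - origin[1]) <= max(radius, 1.0):
        n_ext += 1
    if n_ext > n0:
        window = daily.iloc[:n_ext]
        origin, radius = _fit(window)
    return (float(origin[0]), float(origin[1])), radius


def _plateau_days(series: NsdSeries, lo: int, hi: int, params: SegmentationParams) -> np.ndarray:
    """Boolean mask over series[lo:hi]: day belongs to a low-CV NSD window."""
    days = series.days[lo:hi]
    nsd = series.nsd_km2[lo:hi]
    n = len(days)
    mask = np.zeros(n, dtype=bool)
    half = params.plateau_window_days // 2
    day_num = (days - days[0]).days.to_numpy() if n else np.array([])
    for i in range(n):
        sel = (day_num >= day_num[i] - half) & (day_num <= day_num[i] + half)
        if sel.sum() < max(3, params.plateau_window_days // 2):
            continue
        w = nsd[sel]
        m = w.mean()
        if m <= 0:
            continue
        if w.std() / m > params.plateau_cv_max:
            continue
        # trend guard: at high NSD a steady climb can have a small CV purely
        # because the level is large; a plateau must also be trend-free
        dd = day_num[sel]
        slope = np.polyfit(dd, w, 1)[0]
        if abs(slope) * params.plateau_window_days / m > params.plateau_cv_max:
            continue
        mask[i] = True
    return mask


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs (stop exclusive)."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def classify_states(
    series: NsdSeries,
    natal_radius_m: float,
    params: SegmentationParams | None = None,
) -> list[StateSegment]:
    """Scan the daily NSD sequence into dispersal-state segments.

    See the module docstring for the operational definitions.  Returned
    segments partition the classified span of days (inclusive endpoints,
    calendar days).
    """
    params = params or SegmentationParams()
    n = len(series)
    if n == 0:
        return []
    thr = params.return_threshold * (natal_radius_m / 1000.0) ** 2
    thr = max(thr, 1e-12)
    out = series.nsd_km2 > thr
    days = series.days

    def span_days(i, j):
        """Calendar-day span of run series[i:j]."""
        return (days[j - 1] - days[i]).days + 1

    labels = np.empty(n, dtype=object)
    labels[:] = "natal"
    runs = _runs(out)
    departure_run = None
    for (i, j) in runs:
        if j == n:  # never re-enters: departure
            if span_days(i, j) >= params.away_min_days:
                departure_run = (i, j)
            else:
                # too short to call; left as travel anyway (no return observed)
                departure_run = (i, j)
        else:
            if span_days(i, j) >= params.away_min_days:
                labels[i:j] = "exploratory"
            # shorter sallies stay natal (precedence natal > travel)

    if departure_run is not None:
        i, j = departure_run
        labels[i:j] = "departure"
        # plateau search within the post-departure span
        pmask = _plateau_days(series, i, j, params)
        refined = []
        for (a, b) in _runs(pmask):
            a0, b0 = i + a, i + b
            # refine: extend the plateau backward/forward while NSD stays
            # within the plateau band (the sliding-CV mask lags the true
            # arrival by up to half a window)
            core = series.nsd_km2[a0:b0]
            m, s = core.mean(), core.std()
            band = max(2 * s, 0.1 * m)
            while a0 > i and abs(series.nsd_km2[a0 - 1] - m) <= band:
                a0 -= 1
            while b0 < j and abs(series.nsd_km2[b0] - m) <= band:
                b0 += 1
            refined.append([a0, b0])
        # merge runs split by 1-2 noisy days, then absorb a short tail at
        # collar drop into the final plateau
        merged: list[list[int]] = []
        for run in refined:
            if merged and run[0] - merged[-1][1] <= 2:
                merged[-1][1] = max(merged[-1][1], run[1])
            else:
                merged.append(run)
        if merged and j == n and 0 < j - merged[-1][1] <= params.away_min_days:
            # a sub-week tail at collar drop whose NSD level still matches
            # the plateau (NSD scales with distance squared, so a modest
            # relative change is a small change in distance) is the same
            # range, not renewed travel
            a0, b0 = merged[-1]
            m_core = series.nsd_km2[a0:b0].mean()
            m_tail = series.nsd_km2[b0:j].mean()
            if m_core > 0 and abs(m_tail - m_core) / m_core <= 2 * params.plateau_cv_max:
                merged[-1][1] = j
        for a0, b0 in merged:
            dur = span_days(a0, b0)
            if dur < params.plateau_min_days:
                continue
            if dur >= params.transient_max_days:
                labels[a0:b0] = "established"
            else:
                labels[a0:b0] = "transient_home_range"

    # assemble contiguous segments
    segments: list[StateSegment] = []
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        segments.append(StateSegment(
            animal_id=series.animal_id,
            state=str(labels[i]),
            t_start=days[i],
            t_end=days[j - 1],
            duration_days=(days[j - 1] - days[i]).days + 1,
        ))
        i = j
    return segments


def summarize_states(
    segments: list[StateSegment],
    fixes: pd.DataFrame,
    origin: tuple[float, float],
) -> pd.DataFrame:
    """Per-segment movement summaries.

    path_km: cumulative distance over consecutive fixes inside the segment;
    displacement_km: straight-line distance from the natal origin to the
    segment's last fix.
    """
    fixes = fixes.sort_values("t").reset_index(drop=True)
    rows = []
    for seg in segments:
        sel = (fixes["t"] >= seg.t_start) & (fixes["t"] < seg.t_end + pd.Timedelta(days=1))
        sub = fixes[sel]
        if len(sub) >= 2:
            path = float(np.hypot(np.diff(sub["x"]), np.diff(sub["y"])).sum() / 1000.0)
        else:
            path = 0.0
        if len(sub) >= 1:
            disp = float(np.hypot(sub["x"].iloc[-1] - origin[0],
                                  sub["y"].iloc[-1] - origin[1]) / 1000.0)
        else:
            disp = float("nan")
        seg.path_km = path
        seg.displacement_km = disp
        rows.append({
            "animal_id": seg.animal_id, "state": seg.state,
            "t_start": seg.t_start, "t_end": seg.t_end,
            "duration_days": seg.duration_days,
            "path_km": path, "displacement_km": disp,
        })
    return pd.DataFrame(rows)


def segments_to_frame(segments: list[StateSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "animal_id": s.animal_id, "state": s.state, "t_start": s.t_start,
        "t_end": s.t_end, "duration_days": s.duration_days,
        "path_km": s.path_km, "displacement_km": s.displacement_km,
    } for s in segments])
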