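"""Raw GPS fixes -> analysis-ready step bursts.

A *burst* is a maximal run of fixes at a uniform nominal interval (within a
tolerance window); steps are only formed within bursts.  Preprocessing
comprises: ingest with per-row validation, greedy-forward resampling to a
target fix rate (e.g. 1-2 h collars resampled to 4 h), kill-site cluster
detection and removal (so stationary feeding behavior does not bias
movement-based selection estimates), and trimming of the transition period
at the start of each behavioral state.

All timestamps are UTC; time comparisons use half-open intervals
``[start, end)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Burst",
    "ClusterEvent",
    "ingest_fixes",
    "resample_track",
    "detect_clusters",
    "remove_clusters",
    "trim_transition",
    "write_bursts",
]

MIN_BURST_FIXES = 3  # minimum to form one step with a turning angle


@dataclass(eq=False)
class Burst:
    animal_id: str
    fixes: pd.DataFrame  # columns t, x, y (time-sorted)
    nominal_interval_min: float
    state_label: str | None = None

    def __post_init__(self) -> None:
        self.fixes = self.fixes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class ClusterEvent:
    animal_id: str
    member_fix_indices: list[int]
    centroid_x: float
    centroid_y: float
    t_start: pd.Timestamp
    t_end: pd.Timestamp

    @property
    def first(self) -> int:
        return self.member_fix_indices[0]

    @property
    def last(self) -> int:
        return self.member_fix_indices[-1]


def ingest_fixes(path, column_map: dict[str, str] | None = None) -> dict[str, pd.DataFrame]:
    """Read delimited telemetry into per-animal, time-sorted fix tables.

    ``column_map`` maps the required names {animal_id, t, x, y} to the
    file's column names.  Rows with unparseable timestamps or non-numeric
    coordinates are rejected and logged with their row numbers; more than
    50% rejects is a hard error.  Exact-duplicate timestamps within an
    animal collapse to the first row.
    """
    cmap = {"animal_id": "animal_id", "t": "t", "x": "x", "y": "y"}
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    if raw.empty:
        warnings.warn(f"{path}: empty telemetry file")
        return {}
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"columns not found in {path}: {missing}")
    df = pd.DataFrame({
        "animal_id": raw[cmap["animal_id"]].astype(str),
        "t": pd.to_datetime(raw[cmap["t"]], utc=True, errors="coerce", format="mixed"),
        "x": pd.to_numeric(raw[cmap["x"]], errors="coerce"),
        "y": pd.to_numeric(raw[cmap["y"]], errors="coerce"),
    })
    bad = df[["t", "x", "y"]].isna().any(axis=1) | ~np.isfinite(df[["x", "y"]]).all(axis=1)
    if bad.any():
        for i in df.index[bad]:
            log.warning("%s: rejected row %d (unparseable timestamp or coordinate)", path, i + 2)
        if bad.mean() > 0.5:
            raise ValueError(f"{path}: more than 50% of rows rejected ({int(bad.sum())}/{len(df)})")
    df = df[~bad]
    out: dict[str, pd.DataFrame] = {}
    for animal, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("t", kind="stable").drop_duplicates(subset="t", keep="first")
        out[str(animal)] = grp[["t", "x", "y"]].reset_index(drop=True)
    return out


def resample_track(
    fixes: pd.DataFrame,
    target_interval_min: float = 240.0,
    tolerance_min: float = 10.0,
    animal_id: str = "animal",
) -> list[Burst]:
    """Regularize fixes to a target interval by a greedy forward pass.

    From the current anchor fix, the earliest subsequent fix whose gap lies
    in ``[target - tol, target + tol]`` is accepted and becomes the new
    anchor; failure to find one closes the burst, and the next fix in time
    starts a new one.  Bursts with fewer than 3 fixes are discarded.
    """
    if target_interval_min <= 0 or tolerance_min <= 0:
        raise ValueError("interval and tolerance must be positive")
    fixes = fixes.reset_index(drop=True)
    n = len(fixes)
    if n == 0:
        return []
    tns = fixes["t"].astype("int64").to_numpy()
    minutes = (tns - tns[0]) / 60e9
    lo, hi = target_interval_min - tolerance_min, target_interval_min + tolerance_min

    bursts: list[Burst] = []
    current = [0]
    anchor = 0
    i = anchor + 1
    while True:
        # find earliest fix within the window of the anchor
        j = anchor + 1
        accept = -1
        while j < n:
            gap = minutes[j] - minutes[anchor]
            if gap > hi:
                break
            if gap >= lo:
                accept = j
                break
            j += 1
        if accept >= 0:
            current.append(accept)
            anchor = accept
        else:
            if len(current) >= MIN_BURST_FIXES:
                bursts.append(Burst(animal_id, fixes.iloc[current], target_interval_min))
            nxt = anchor + 1
            if nxt >= n:
                break
            current = [nxt]
            anchor = nxt
        if anchor + 1 >= n:
            if len(current) >= MIN_BURST_FIXES:
                bursts.append(Burst(animal_id, fixes.iloc[current], target_interval_min))
            break
    return bursts


def detect_clusters(
    burst: Burst,
    min_fix_count: int = 4,
    spatial_buffer_m: float = 150.0,
    temporal_buffer_h: float = 24.0,
) -> list[ClusterEvent]:
    """Sequential-scan kill-site cluster detection.

    A candidate cluster opens at any fix; a subsequent fix joins if it lies
    within ``spatial_buffer_m`` of the running centroid and within
    ``temporal_buffer_h`` of the cluster's last member (the temporal buffer
    is a maximum revisit gap, not a total span).  Candidates with at least
    ``min_fix_count`` members are emitted; emitted clusters do not overlap
    (the scan resumes after the cluster's last member).
    """
    fixes = burst.fixes
    n = len(fixes)
    t = fixes["t"].astype("int64").to_numpy()  # ns since epoch
    xy = fixes[["x", "y"]].to_numpy(dtype=float)
    buf_ns = int(temporal_buffer_h * 3600 * 1e9)
    clusters: list[ClusterEvent] = []
    start = 0
    while start < n:
        members = [start]
        cx, cy = xy[start]
        j = start + 1
        while j < n:
            if t[j] - t[members[-1]] > buf_ns:
                break
            if np.hypot(xy[j, 0] - cx, xy[j, 1] - cy) <= spatial_buffer_m:
                members.append(j)
                cx, cy = xy[members].mean(axis=0)
            j += 1
        if len(members) >= min_fix_count:
            clusters.append(ClusterEvent(
                animal_id=burst.animal_id,
                member_fix_indices=members,
                centroid_x=float(cx),
                centroid_y=float(cy),
                t_start=fixes["t"].iloc[members[0]],
                t_end=fixes["t"].iloc[members[-1]],
            ))
            start = members[-1] + 1
        else:
            start += 1
    return clusters


def remove_clusters(burst: Burst, clusters: list[ClusterEvent]) -> list[Burst]:
    """Split a burst at detected clusters.

    The cluster's first fix terminates the preceding burst and its last fix
    begins the following burst, so no step ever spans a cluster interior;
    every fix strictly between them is dropped.  Resulting fragments with
    fewer than 3 fixes are discarded.
    """
    n = len(burst.fixes)
    for c in clusters:
        if c.first < 0 or c.last >= n:
            raise ValueError("cluster indices out of range for this burst")
    if not clusters:
        return [burst]
    clusters = sorted(clusters, key=lambda c: c.first)
    pieces: list[Burst] = []
    seg_start = 0
    for c in clusters:
        idx = list(range(seg_start, c.first + 1))
        if len(idx) >= MIN_BURST_FIXES:
            pieces.append(Burst(burst.animal_id, burst.fixes.iloc[idx],
                                burst.nominal_interval_min, burst.state_label))
        seg_start = c.last
    idx = list(range(seg_start, n))
    if len(idx) >= MIN_BURST_FIXES:
        pieces.append(Burst(burst.animal_id, burst.fixes.iloc[idx],
                            burst.nominal_interval_min, burst.state_label))
    return pieces


def trim_transition(
    burst_list: list[Burst],
    t_start: pd.Timestamp,
    t_end: pd.Timestamp,
    trim_days: float = 3.0,
) -> list[Burst]:
    """Restrict bursts to a state segment, dropping its transition period.

    Fixes in ``[t_start, t_start + trim_days)`` are removed and the
    remainder of ``[t_start, t_end)`` is re-bursted (a burst straddling the
    trim boundary is split there).  Returns possibly-empty list; an empty
    result (trim longer than the segment) warns.
    """
    cut = pd.Timestamp(t_start) + pd.Timedelta(days=trim_days)
    out: list[Burst] = []
    for b in burst_list:
        keep = (b.fixes["t"] >= cut) & (b.fixes["t"] < pd.Timestamp(t_end))
        if keep.sum() >= MIN_BURST_FIXES:
            out.append(Burst(b.animal_id, b.fixes[keep], b.nominal_interval_min, b.state_label))
    if not out:
        warnings.warn("trim_transition: no fixes remain in the segment after trimming")
    return out


def write_bursts(path, bursts: list[Burst]) -> None:
    """Write bursts as delimited text with a burst_id column."""
    frames = []
    for i, b in enumerate(bursts):
        df = b.fixes.copy()
        df.insert(0, "burst_id", i)
        df.insert(0, "animal_id", b.animal_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
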