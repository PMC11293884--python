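import numpy as np
import pandas as pd
import pytest

from dispersalkit.nsd import (
    NatalRangeError,
    NsdSeries,
    SegmentationParams,
    classify_states,
    compute_nsd,
    estimate_natal_range,
    summarize_states,
)

from conftest import make_fixes


def _series(nsd, t0="2022-01-01", animal="a"):
    days = pd.DatetimeIndex([pd.Timestamp(t0, tz="UTC") + pd.Timedelta(days=i)
                             for i in range(len(nsd))])
    nsd = np.asarray(nsd, dtype=float)
    return NsdSeries(animal_id=animal, origin=(0.0, 0.0), days=days,
                     nsd_km2=nsd, x=np.zeros(len(nsd)), y=np.zeros(len(nsd)))


class TestComputeNsd:
    def test_single_fix_at_origin_is_zero(self):
        fixes = make_fixes([12.0], [(0, 0)])
        series = compute_nsd(fixes, (0.0, 0.0))
        assert list(series.nsd_km2) == [0.0]

    def test_three_four_five_triangle(self):
        fixes = make_fixes([12.0], [(3000.0, 4000.0)])
        series = compute_nsd(fixes, (0.0, 0.0))
        assert series.nsd_km2[0] == pytest.approx(25.0)

    def test_fix_nearest_noon_chosen(self):
        # 09:00 (3 h from noon) wins over 16:00 (4 h from noon)
        fixes = make_fixes([9.0, 16.0], [(1000.0, 0.0), (2000.0, 0.0)])
        series = compute_nsd(fixes, (0.0, 0.0))
        assert len(series) == 1
        assert series.nsd_km2[0] == pytest.approx(1.0)

    def test_days_without_fixes_absent(self):
        fixes = make_fixes([12.0, 12.0 + 72.0], [(0, 0), (1000.0, 0)])
        series = compute_nsd(fixes, (0.0, 0.0))
        assert len(series) == 2
        assert (series.days[1] - series.days[0]).days == 3


class TestEstimateNatalRange:
    def test_uniform_disc_recovers_center_and_quantile_radius(self):
        rng = np.random.default_rng(11)
        n_days = 40
        r = 2000.0 * np.sqrt(rng.uniform(size=n_days))
        th = rng.uniform(0, 2 * np.pi, n_days)
        xy = [(5000 + ri * np.cos(t), 7000 + ri * np.sin(t)) for ri, t in zip(r, th)]
        fixes = make_fixes(np.arange(n_days) * 24.0 + 12.0, xy)
        origin, radius = estimate_natal_range(fixes)
        assert np.hypot(origin[0] - 5000, origin[1] - 7000) < 500
        d = np.hypot([p[0] - origin[0] for p in xy], [p[1] - origin[1] for p in xy])
        assert radius == pytest.approx(np.quantile(d, 0.95), rel=0.05)

    def test_monotone_drift_flagged(self):
        # no residency plateau: mirrors excluding collared animals that
        # never displayed home-ranging behavior around the capture site
        xy = [(i * 1000.0, 0.0) for i in range(40)]
        fixes = make_fixes(np.arange(40) * 24.0 + 12.0, xy)
        with pytest.raises(NatalRangeError, match="plateau"):
            estimate_natal_range(fixes)

    def test_all_fixes_at_one_point(self):
        fixes = make_fixes(np.arange(35) * 24.0 + 12.0, [(100.0, 200.0)] * 35)
        origin, radius = estimate_natal_range(fixes)
        assert origin == (100.0, 200.0)
        assert radius == 0.0

    def test_insufficient_data_flagged(self):
        fixes = make_fixes(np.arange(10) * 24.0 + 12.0, [(0.0, 0.0)] * 10)
        with pytest.raises(NatalRangeError, match="days"):
            estimate_natal_range(fixes)


class TestClassifyStates:
    def test_excursion_with_return_is_exploratory(self):
        rng = np.random.default_rng(12)
        nsd = np.concatenate([
            np.abs(rng.normal(0.5, 0.2, 30)),       # natal plateau
            np.linspace(1, 400, 15),                 # ramp out
            rng.normal(400, 10, 30),                 # high plateau (mid-excursion)
            np.linspace(400, 1, 15),                 # ramp back
            np.abs(rng.normal(0.5, 0.2, 20)),        # home again
        ])
        segs = classify_states(_series(nsd), natal_radius_m=1200.0)
        states = [s.state for s in segs]
        assert states == ["natal", "exploratory", "natal"]
        # the excursion covers ramp-up through return, not just the plateau
        assert segs[1].duration_days >= 56

    def test_monotone_ramp_without_return_is_departure(self):
        rng = np.random.default_rng(13)
        nsd = np.concatenate([
            np.abs(rng.normal(0.5, 0.2, 30)),
            np.linspace(1, 900, 40),
        ])
        segs = classify_states(_series(nsd), natal_radius_m=1200.0)
        assert [s.state for s in segs] == ["natal", "departure"]

    def test_postdeparture_plateau_under_six_months_is_transient(self):
        rng = np.random.default_rng(14)
        nsd = np.concatenate([
            np.abs(rng.normal(0.5, 0.2, 30)),
            np.linspace(1, 2500, 20),
            rng.normal(2500, 60, 120),               # ~4-month plateau, then collar ends
        ])
        segs = classify_states(_series(nsd), natal_radius_m=1200.0)
        assert [s.state for s in segs] == ["natal", "departure", "transient_home_range"]

    def test_postdeparture_plateau_over_six_months_is_established(self):
        rng = np.random.default_rng(15)
        nsd = np.concatenate([
            np.abs(rng.normal(0.5, 0.2, 30)),
            np.linspace(1, 2500, 20),
            rng.normal(2500, 60, 200),               # > 183 days of plateau
        ])
        segs = classify_states(_series(nsd), natal_radius_m=1200.0)
        assert segs[-1].state == "established"

    def test_short_sally_stays_natal(self):
        rng = np.random.default_rng(16)
        nsd = np.abs(rng.normal(0.5, 0.2, 60))
        nsd[30:33] = 50.0  # 3-day excursion, below away_min_days
        segs = classify_states(_series(nsd), natal_radius_m=1200.0)
        assert [s.state for s in segs] == ["natal"]

    def test_segments_partition_the_series(self):
        rng = np.random.default_rng(17)
        nsd = np.concatenate([
            np.abs(rng.normal(0.5, 0.2, 30)),
            np.linspace(1, 400, 12), rng.normal(400, 10, 10), np.linspace(400, 1, 12),
            np.abs(rng.normal(0.5, 0.2, 10)),
            np.linspace(1, 2500, 20), rng.normal(2500, 60, 80),
        ])
        series = _series(nsd)
        segs = classify_states(series, natal_radius_m=1200.0)
        assert segs[0].t_start == series.days[0]
        assert segs[-1].t_end == series.days[-1]
        for a, b in zip(segs[:-1], segs[1:]):
            assert b.t_start == a.t_end + pd.Timedelta(days=1)

    def test_raising_return_threshold_never_shrinks_natal_days(self):
        rng = np.random.default_rng(18)
        nsd = np.concatenate([
            np.abs(rng.normal(0.5, 0.3, 30)),
            np.linspace(1, 400, 15), rng.normal(400, 10, 20), np.linspace(400, 1, 15),
            np.abs(rng.normal(0.5, 0.3, 20)),
        ])
        series = _series(nsd)

        def natal_days(thr):
            params = SegmentationParams(return_threshold=thr)
            return sum(s.duration_days for s in
                       classify_states(series, 1200.0, params) if s.state == "natal")

        assert natal_days(2.0) >= natal_days(1.0)


class TestSummarizeStates:
    def test_straight_march_path_equals_displacement(self):
        # 10 days marching due east at 1 km/day (4-h fixes), one segment
        hours = np.arange(0, 244, 4.0)
        xy = [(1000.0 + h * 1000.0 / 24.0, 0.0) for h in hours]
        fixes = make_fixes(hours, xy)
        series = compute_nsd(fixes, (0.0, 0.0))
        segs = classify_states(series, natal_radius_m=100.0)
        summary = summarize_states(segs, fixes, (0.0, 0.0))
        assert summary["path_km"].sum() == pytest.approx(10.0, rel=0.01)
        assert summary["displacement_km"].iloc[-1] == pytest.approx(11.0, rel=0.01)

    def test_closed_loop_has_path_but_no_displacement(self):
        th = np.linspace(0, 2 * np.pi, 20)
        xy = [(3000 * np.cos(t), 3000 * np.sin(t)) for t in th]
        fixes = make_fixes(np.arange(20) * 4.0, xy)
        seg = classify_states(
            compute_nsd(fixes, (3000.0, 0.0)), natal_radius_m=10000.0)
        summary = summarize_states(seg, fixes, (3000.0, 0.0))
        assert summary["path_km"].sum() > 10.0
        assert summary["displacement_km"].iloc[-1] < 0.5
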