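import numpy as np
import pandas as pd
import pytest

from dispersalkit.preprocess import (
    Burst,
    detect_clusters,
    ingest_fixes,
    remove_clusters,
    resample_track,
    trim_transition,
)

from conftest import make_fixes


class TestIngest:
    def _write(self, tmp_path, text):
        p = tmp_path / "fixes.csv"
        p.write_text(text)
        return p

    def test_duplicate_timestamp_collapsed(self, tmp_path):
        p = self._write(tmp_path,
                        "animal_id,t,x,y\n"
                        "a,2022-01-01T00:00:00Z,0,0\n"
                        "a,2022-01-01T00:00:00Z,5,5\n"
                        "a,2022-01-01T04:00:00Z,10,0\n")
        out = ingest_fixes(p)
        assert len(out["a"]) == 2
        assert out["a"]["x"].iloc[0] == 0  # first kept

    def test_out_of_order_rows_sorted(self, tmp_path):
        p = self._write(tmp_path,
                        "animal_id,t,x,y\n"
                        "a,2022-01-01T08:00:00Z,2,0\n"
                        "a,2022-01-01T00:00:00Z,0,0\n"
                        "a,2022-01-01T04:00:00Z,1,0\n")
        out = ingest_fixes(p)
        assert list(out["a"]["x"]) == [0, 1, 2]

    def test_empty_file_warns_not_errors(self, tmp_path):
        p = self._write(tmp_path, "animal_id,t,x,y\n")
        with pytest.warns(UserWarning, match="empty"):
            out = ingest_fixes(p)
        assert out == {}

    def test_bad_rows_rejected(self, tmp_path):
        p = self._write(tmp_path,
                        "animal_id,t,x,y\n"
                        "a,not-a-time,0,0\n"
                        "a,2022-01-01T00:00:00Z,zzz,0\n"
                        "a,2022-01-01T04:00:00Z,1,1\n"
                        "a,2022-01-01T08:00:00Z,2,2\n"
                        "a,2022-01-01T12:00:00Z,3,3\n")
        out = ingest_fixes(p)
        assert len(out["a"]) == 3

    def test_majority_bad_rows_is_hard_error(self, tmp_path):
        p = self._write(tmp_path,
                        "animal_id,t,x,y\n"
                        "a,bad,0,0\n"
                        "a,bad,1,1\n"
                        "a,2022-01-01T00:00:00Z,2,2\n")
        with pytest.raises(ValueError, match="50%"):
            ingest_fixes(p)

    def test_column_map(self, tmp_path):
        p = self._write(tmp_path,
                        "id,stamp,easting,northing\n"
                        "a,2022-01-01T00:00:00Z,1,2\n"
                        "a,2022-01-01T04:00:00Z,3,4\n")
        out = ingest_fixes(p, column_map={"animal_id": "id", "t": "stamp",
                                          "x": "easting", "y": "northing"})
        assert list(out["a"]["y"]) == [2, 4]


class TestResample:
    def test_hourly_fixes_to_four_hours_keeps_every_fourth(self):
        fixes = make_fixes(np.arange(0, 48, 1.0), [(i, 0) for i in range(48)])
        bursts = resample_track(fixes, 240.0, 10.0)
        assert len(bursts) == 1
        assert list(bursts[0].fixes["x"]) == list(range(0, 48, 4))

    def test_gap_splits_into_two_bursts(self):
        hours = list(np.arange(0, 24, 4.0)) + list(np.arange(29, 53, 4.0))
        fixes = make_fixes(hours, [(i, 0) for i in range(len(hours))])
        bursts = resample_track(fixes, 240.0, 10.0)
        assert len(bursts) == 2
        assert len(bursts[0]) == 6 and len(bursts[1]) == 6

    def test_fix_at_247_minutes_accepted(self):
        fixes = make_fixes([0, 247 / 60, 2 * 247 / 60], [(0, 0), (1, 0), (2, 0)])
        bursts = resample_track(fixes, 240.0, 10.0)
        assert len(bursts) == 1 and len(bursts[0]) == 3

    def test_fix_at_251_minutes_breaks_burst(self):
        fixes = make_fixes([0, 251 / 60, 2 * 251 / 60], [(0, 0), (1, 0), (2, 0)])
        assert resample_track(fixes, 240.0, 10.0) == []

    def test_resampling_regular_burst_is_identity(self):
        fixes = make_fixes(np.arange(0, 40, 4.0), [(i, i) for i in range(10)])
        once = resample_track(fixes, 240.0, 10.0)
        again = resample_track(once[0].fixes, 240.0, 10.0)
        assert len(again) == 1
        pd.testing.assert_frame_equal(once[0].fixes, again[0].fixes)

    def test_nonpositive_parameters_rejected(self):
        fixes = make_fixes([0, 4], [(0, 0), (1, 0)])
        with pytest.raises(ValueError):
            resample_track(fixes, -240.0, 10.0)
        with pytest.raises(ValueError):
            resample_track(fixes, 240.0, 0.0)


class TestDetectClusters:
    def test_four_identical_fixes_form_one_cluster(self):
        fixes = make_fixes([0, 4, 8, 16], [(100, 100)] * 4)
        b = Burst("a", fixes, 240.0)
        clusters = detect_clusters(b)
        assert len(clusters) == 1
        assert clusters[0].member_fix_indices == [0, 1, 2, 3]

    def test_temporal_buffer_violation_breaks_cluster(self):
        # third fix 30 h after the second: the candidate dies at 2 members
        fixes = make_fixes([0, 4, 34, 38], [(100, 100)] * 4)
        assert detect_clusters(Burst("a", fixes, 240.0)) == []

    def test_fixes_beyond_spatial_buffer_excluded(self):
        xy = [(0, 0), (40, 0), (500, 0), (20, 0), (10, 0)]
        fixes = make_fixes([0, 4, 8, 12, 16], xy)
        clusters = detect_clusters(Burst("a", fixes, 240.0))
        assert len(clusters) == 1
        assert clusters[0].member_fix_indices == [0, 1, 3, 4]

    def test_spread_over_150m_yields_no_cluster(self):
        # consecutive fixes >= 151 m apart can never join a running centroid
        xy = [(i * 200.0, 0) for i in range(5)]
        fixes = make_fixes([0, 4, 8, 12, 16], xy)
        assert detect_clusters(Burst("a", fixes, 240.0)) == []

    def test_fewer_than_min_fix_count_is_no_cluster(self):
        fixes = make_fixes([0, 4, 8], [(100, 100)] * 3)
        assert detect_clusters(Burst("a", fixes, 240.0)) == []


class TestRemoveClusters:
    def _burst(self, n=10):
        # fixes far apart except a 4-fix clump at indices 3..6
        xy = []
        for i in range(n):
            if 3 <= i <= 6:
                xy.append((3000.0 + (i - 3) * 10, 0.0))
            else:
                xy.append((i * 1000.0, 0.0))
        return Burst("a", make_fixes(np.arange(n) * 4.0, xy), 240.0)

    def test_interior_cluster_splits_burst_at_first_and_last_member(self):
        b = self._burst()
        clusters = detect_clusters(b)
        assert len(clusters) == 1 and clusters[0].member_fix_indices == [3, 4, 5, 6]
        pieces = remove_clusters(b, clusters)
        assert len(pieces) == 2
        assert len(pieces[0]) == 4 and len(pieces[1]) == 4
        # the split shares the cluster's first/last fix with the two pieces
        assert pieces[0].fixes["x"].iloc[-1] == b.fixes["x"].iloc[3]
        assert pieces[1].fixes["x"].iloc[0] == b.fixes["x"].iloc[6]

    def test_no_clusters_returns_burst_unchanged(self):
        b = self._burst()
        out = remove_clusters(b, [])
        assert len(out) == 1 and out[0] is b

    def test_cluster_at_burst_start_leaves_only_trailing_piece(self):
        xy = [(0.0, 0.0)] * 4 + [(i * 1000.0, 0.0) for i in range(1, 5)]
        b = Burst("a", make_fixes(np.arange(8) * 4.0, xy), 240.0)
        clusters = detect_clusters(b)
        pieces = remove_clusters(b, clusters)
        assert len(pieces) == 1
        assert len(pieces[0]) == 5  # last cluster fix + 4 travelling fixes

    def test_out_of_range_cluster_rejected(self):
        b = self._burst()
        clusters = detect_clusters(b)
        clusters[0].member_fix_indices.append(99)
        with pytest.raises(ValueError, match="out of range"):
            remove_clusters(b, clusters)

    def test_never_more_fixes_out_than_in(self):
        b = self._burst(20)
        pieces = remove_clusters(b, detect_clusters(b))
        assert sum(len(p) for p in pieces) <= len(b)


class TestTrimTransition:
    def test_three_day_trim_keeps_seven_of_ten_days(self):
        hours = np.arange(0, 240, 4.0)  # 10 days
        fixes = make_fixes(hours, [(h, 0) for h in hours])
        b = Burst("a", fixes, 240.0)
        t0 = fixes["t"].iloc[0]
        out = trim_transition([b], t0, t0 + pd.Timedelta(days=10))
        kept = pd.concat([p.fixes for p in out])
        assert kept["t"].min() >= t0 + pd.Timedelta(days=3)
        span = (kept["t"].max() - kept["t"].min()).total_seconds() / 86400
        assert span == pytest.approx(7.0, abs=0.2)

    def test_trim_longer_than_segment_warns_and_empties(self):
        hours = np.arange(0, 48, 4.0)  # 2 days
        fixes = make_fixes(hours, [(h, 0) for h in hours])
        b = Burst("a", fixes, 240.0)
        t0 = fixes["t"].iloc[0]
        with pytest.warns(UserWarning, match="no fixes"):
            out = trim_transition([b], t0, t0 + pd.Timedelta(days=2))
        assert out == []
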