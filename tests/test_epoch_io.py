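"""Epoch CSV I/O, noon-to-noon segmentation and cohort inclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from actijive import epoch, simulate
from conftest import make_series


def _write_epoch_csv(tmp_path, rows, header="subject,timestamp,count,wear"):
    path = tmp_path / "epochs.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadEpochs:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        series = [make_series(f"S{i}", n_days=2,
                              counts=rng.integers(0, 500, 2880).astype(float))
                  for i in range(3)]
        series[1].wear[100:300] = False
        path = tmp_path / "rt.csv"
        epoch.write_epochs(series, path)
        back = epoch.read_epochs(path)
        assert [s.subject_id for s in back] == ["S0", "S1", "S2"]
        for a, b in zip(series, back):
            assert a.start == b.start
            # non-wear minutes round-trip as count 0 / wear False
            np.testing.assert_allclose(np.where(a.wear, a.counts, a.counts), b.counts)
            np.testing.assert_array_equal(a.wear, b.wear)

    def test_negative_count_rejected_with_row(self, tmp_path):
        path = _write_epoch_csv(tmp_path, [
            "A,2020-01-06T12:00,5,1",
            "A,2020-01-06T12:01,-3,1",
        ])
        with pytest.raises(ValueError, match="row 3"):
            epoch.read_epochs(path)

    def test_duplicated_minute_rejected(self, tmp_path):
        path = _write_epoch_csv(tmp_path, [
            "A,2020-01-06T12:00,5,1",
            "A,2020-01-06T12:00,7,1",
        ])
        with pytest.raises(ValueError, match="duplicated minute"):
            epoch.read_epochs(path)

    def test_unparseable_timestamp_rejected(self, tmp_path):
        path = _write_epoch_csv(tmp_path, ["A,not-a-time,5,1"])
        with pytest.raises(ValueError, match="timestamp"):
            epoch.read_epochs(path)

    def test_gaps_filled_as_nonwear(self, tmp_path):
        path = _write_epoch_csv(tmp_path, [
            "A,2020-01-06T12:00,5,1",
            "A,2020-01-06T12:03,7,1",
        ])
        (s,) = epoch.read_epochs(path)
        assert s.n_minutes == 4
        np.testing.assert_array_equal(s.wear, [True, False, False, True])
        np.testing.assert_allclose(s.counts, [5, 0, 0, 7])

    def test_missing_wear_column_inferred(self, tmp_path):
        path = _write_epoch_csv(tmp_path, [
            "A,2020-01-06T12:00,5",
            "A,2020-01-06T12:01,",
            "A,2020-01-06T12:02,7",
        ], header="subject,timestamp,count")
        (s,) = epoch.read_epochs(path)
        np.testing.assert_array_equal(s.wear, [True, False, True])

    def test_fourteen_day_synthetic_subject_length(self):
        plan = simulate.EpochPlan(n_subjects=1, n_days=14)
        series, _, _ = simulate.generate_epoch_cohort(plan, 0)
        assert series[0].n_minutes == 14 * 1440 == 20160


class TestSegmentDays:
    def test_windows_partition_every_minute(self):
        # start off-noon so leading/trailing windows are partial
        s = make_series(n_days=3, start="2020-01-06 15:23")
        windows = epoch.segment_days(s)
        covered = np.zeros(s.n_minutes, dtype=int)
        for w in windows:
            covered[w.start_idx:w.stop_idx] += 1
        assert (covered == 1).all()
        assert all(not w.valid for w in windows if not w.complete)

    def test_wear_boundary_961_valid_960_invalid(self):
        for wear_min, expect in [(961, True), (960, False)]:
            wear = np.zeros(1440, dtype=bool)
            wear[:wear_min] = True
            s = make_series(counts=np.full(1440, 10.0), wear=wear)
            (w,) = epoch.segment_days(s)
            assert w.wear_minutes == wear_min
            assert w.valid is expect

    def test_full_wear_fourteen_days_all_valid(self):
        s = make_series(n_days=14)
        windows = epoch.segment_days(s)
        assert len(windows) == 14
        assert sum(w.valid for w in windows) == 14

    def test_day_grid_pads_partial_windows(self):
        s = make_series(counts=np.arange(1440.0), start="2020-01-06 13:00")
        windows = epoch.segment_days(s)
        counts, wear = epoch.day_grid(s, windows[0])
        assert counts.size == 1440
        assert not wear[:60].any() and wear[60:].all()
        np.testing.assert_allclose(counts[60:], np.arange(1380.0))


class TestInclusion:
    def _windows(self, valid_days: dict):
        out = {}
        for sid, n_valid in valid_days.items():
            s = make_series(sid, n_days=10)
            ws = epoch.segment_days(s)
            for i, w in enumerate(ws):
                w.valid = i < n_valid
            out[sid] = ws
        return out

    def test_boundary_seven_valid_days(self):
        included, counts = epoch.apply_inclusion(self._windows({"A": 6, "B": 7}))
        assert included == ["B"]
        assert counts == {"A": 6, "B": 7}

    @given(st.dictionaries(st.text(min_size=1, max_size=3),
                           st.integers(0, 10), min_size=1, max_size=8),
           st.integers(1, 9))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_adds_subjects(self, valid_days, k):
        windows = self._windows(valid_days)
        try:
            lo, _ = epoch.apply_inclusion(windows, min_valid_days=k)
        except ValueError:
            lo = []
        try:
            hi, _ = epoch.apply_inclusion(windows, min_valid_days=k + 1)
        except ValueError:
            hi = []
        assert set(hi) <= set(lo)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty"):
            epoch.apply_inclusion(self._windows({"A": 2}), min_valid_days=7)

    def test_planted_dropouts_match_plan(self):
        plan = simulate.EpochPlan(n_subjects=50, n_days=10,
                                  dropout_subjects=12, dropout_days=4)
        series, _, truth = simulate.generate_epoch_cohort(plan, 3)
        windows = {s.subject_id: epoch.segment_days(s) for s in series}
        included, counts = epoch.apply_inclusion(windows, min_valid_days=7)
        assert counts == truth["planned_valid_days"]
        # 10 - 4 = 6 valid days < 7: the planted dropouts are excluded
        assert len(included) == 50 - 12


class TestCovariates:
    def test_read_and_validate(self, tmp_path):
        path = tmp_path / "cov.csv"
        path.write_text(
            "subject,age,sex,bmi,group,anxiety,sud,medication\n"
            "A,63,female,26.3,none,0,0,0\n"
            "B,58,male,27.1,current,1,0,1\n")
        df = epoch.read_covariates(path)
        assert list(df.index) == ["A", "B"]
        assert df.loc["B", "anxiety"] == True  # noqa: E712

    def test_unknown_group_rejected(self, tmp_path):
        path = tmp_path / "cov.csv"
        path.write_text("subject,age,sex,bmi,group,anxiety,sud\n"
                        "A,63,female,26.3,past,0,0\n")
        with pytest.raises(ValueError, match="group"):
            epoch.read_covariates(path)
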