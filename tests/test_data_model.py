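import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import occudyn as od
from occudyn.data_model import ValidationError

from conftest import make_events


class TestReadDetections:
    def test_parses_well_formed_rows(self, tmp_path, two_station_table):
        f = tmp_path / "d.csv"
        f.write_text(
            "station_id,timestamp\na,2014-02-10T08:00\na,2014-02-10T10:30\nb,2014-02-12T23:15\n"
        )
        events = od.read_detections(f, two_station_table)
        assert len(events) == 3
        assert events[0].timestamp == dt.datetime(2014, 2, 10, 8, 0)

    def test_empty_file_with_header(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("station_id,timestamp\n")
        assert od.read_detections(f) == []

    def test_invalid_month_names_row(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("station_id,timestamp\na,2014-02-10T08:00\na,2014-13-01T00:00\n")
        with pytest.raises(ValidationError, match="row 2"):
            od.read_detections(f)

    def test_unknown_station_rejected(self, tmp_path, two_station_table):
        f = tmp_path / "d.csv"
        f.write_text("station_id,timestamp\nzz,2014-02-10T08:00\n")
        with pytest.raises(ValidationError, match="unknown station"):
            od.read_detections(f, two_station_table)


class TestIndependenceFilter:
    def test_greedy_forward_pass(self):
        events = make_events("a", [0, 30, 90])
        kept = od.filter_independent(events, 60)
        assert [e.timestamp.minute + 60 * e.timestamp.hour for e in kept] == [0, 90]

    def test_exactly_at_gap_not_independent(self):
        events = make_events("a", [0, 60])
        assert len(od.filter_independent(events, 60)) == 1

    def test_stations_never_interact(self):
        events = make_events("a", [0]) + make_events("b", [10])
        assert len(od.filter_independent(events, 60)) == 2

    def test_global_mode_pools_stations(self):
        events = make_events("a", [0]) + make_events("b", [10])
        assert len(od.filter_independent(events, 60, per_station=False)) == 1

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 600), max_size=30), st.integers(1, 120))
    def test_idempotent(self, minutes, gap):
        events = make_events("a", minutes)
        once = od.filter_independent(events, gap)
        assert od.filter_independent(once, gap) == once


class TestBuildHistory:
    def test_event_day7_falls_in_second_period(self, two_station_table, design4):
        ev = [od.DetectionEvent("a", dt.datetime(2014, 2, 17, 12, 0))]  # day 7
        h = od.build_history(ev, design4, two_station_table)
        assert h.y[0, 0].tolist() == [0, 1, 0, 0]

    def test_inactive_station_all_missing(self, two_station_table, design4):
        design4.active["winter_2014"] = {"a"}
        try:
            h = od.build_history([], design4, two_station_table)
            t = h.season_labels.index("winter_2014")
            assert np.isnan(h.y[1, t]).all()
            assert h.effort[1, t] == 0
            assert (h.y[0, t] == 0).all()
        finally:
            design4.active.clear()

    def test_two_events_same_period_binary(self, two_station_table, design4):
        ev = [
            od.DetectionEvent("a", dt.datetime(2014, 2, 11, 1, 0)),
            od.DetectionEvent("a", dt.datetime(2014, 2, 12, 2, 0)),
        ]
        h = od.build_history(ev, design4, two_station_table)
        assert h.y[0, 0, 0] == 1

    def test_event_outside_windows_rejected(self, two_station_table, design4):
        ev = [od.DetectionEvent("a", dt.datetime(2014, 5, 1, 0, 0))]
        with pytest.raises(ValidationError, match="outside"):
            od.build_history(ev, design4, two_station_table)


class TestStandardize:
    def test_two_values_sample_sd(self, two_station_table):
        df = two_station_table.df.copy()
        df["elevation"] = [0.0, 10.0]
        std, scaling = od.standardize(od.StationTable(df), ["elevation"])
        assert np.allclose(std.df["elevation"], [-0.70710678, 0.70710678])
        assert scaling.sd["elevation"] == pytest.approx(np.std([0, 10], ddof=1))

    def test_idempotent_up_to_tolerance(self, landscape93):
        std1, _ = od.standardize(landscape93, ["elevation"])
        std2, _ = od.standardize(std1, ["elevation"])
        assert np.allclose(std1.df["elevation"], std2.df["elevation"], atol=1e-12)

    def test_constant_column_errors(self, two_station_table):
        df = two_station_table.df.copy()
        df["slope"] = 3.0
        with pytest.raises(ValidationError, match="slope"):
            od.standardize(od.StationTable(df), ["slope"])

    def test_inverse_recovers_raw(self, landscape93):
        names = ["elevation", "dist_freshwater"]
        std, scaling = od.standardize(landscape93, names)
        for n in names:
            back = scaling.inverse(n, std.df[n].to_numpy())
            assert np.allclose(back, landscape93.df[n], atol=1e-10)


class TestCollinearityScreen:
    def test_monotone_transform_flagged(self, landscape93):
        df = landscape93.df.copy()
        df["slope"] = 2 * df["elevation"] + 5
        flagged = od.collinearity_screen(od.StationTable(df), ["elevation", "slope"])
        assert [(a, b) for a, b, _ in flagged] == [("elevation", "slope")]
        assert flagged[0][2] == pytest.approx(1.0)

    def test_negative_correlation_flagged(self, landscape93):
        df = landscape93.df.copy()
        df["slope"] = -df["elevation"]
        flagged = od.collinearity_screen(od.StationTable(df), ["elevation", "slope"])
        assert abs(flagged[0][2]) == pytest.approx(1.0)

    def test_independent_columns_pass(self, two_station_table):
        rng = np.random.default_rng(0)
        df = pd.concat([two_station_table.df] * 500, ignore_index=True)
        df["id"] = [f"s{i}" for i in range(len(df))]
        df["elevation"] = rng.normal(size=len(df))
        df["slope"] = rng.normal(size=len(df))
        assert od.collinearity_screen(od.StationTable(df), ["elevation", "slope"]) == []


class TestRates:
    def test_capture_rate_direct_ratio(self):
        assert od.capture_rate(4, 200) == pytest.approx(2.0)
        assert od.capture_rate(0, 200) == 0.0
        # the study's summer rate: 193 detections over 1,802 trap nights
        assert od.capture_rate(193, 1802) == pytest.approx(10.71, abs=0.005)

    def test_capture_rate_requires_positive_effort(self):
        with pytest.raises(ValueError):
            od.capture_rate(1, 0)

    def test_distance_binning(self, two_station_table):
        df = two_station_table.df.copy()
        df.loc[0, "dist_freshwater"] = 120.0
        df.loc[1, "dist_freshwater"] = 50.0
        stations = od.StationTable(df)
        events = make_events("a", [0, 100, 300]) + make_events("b", [0])
        table = od.detection_rate_by_distance(
            events, stations, {"a": 100.0, "b": 60.0}, bin_width_m=50
        )
        row_a = table[table.bin_left == 100].iloc[0]
        assert row_a.n_events == 3 and row_a.rate_per_100tn == pytest.approx(3.0)
        # boundary: exactly 50 m goes to [50, 100)
        row_b = table[table.bin_left == 50].iloc[0]
        assert row_b.n_events == 1
        assert row_b.rate_per_100tn == pytest.approx(100 * 1 / 60)
        # zero-effort bins are undefined, not zero
        empty = table[(table.bin_left == 0)]
        assert np.isnan(empty.rate_per_100tn).all()
        assert table.trap_nights.sum() == pytest.approx(160.0)

    def test_three_events_sixty_trapnights(self, two_station_table):
        events = make_events("a", [0, 100, 300])
        table = od.detection_rate_by_distance(events, two_station_table, {"a": 60.0})
        assert table[table.bin_left == 50].iloc[0].rate_per_100tn == pytest.approx(5.0)
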