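"""Quality filtering, hourly binning, monthly metrics and ISO weeks."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from porpoisepam import detection


def _trains_df(rows):
    return pd.DataFrame(rows, columns=["site", "start", "icis", "quality"])


class TestFilterTrains:
    def test_keeps_hi_and_med_in_order(self):
        df = _trains_df(
            [
                ("S", pd.Timestamp("2015-01-01 00:00"), np.full(4, 30e3), q)
                for q in ("Hi", "Low", "Med", "Low")
            ]
        )
        out = detection.filter_trains(df)
        assert list(out["quality"]) == ["Hi", "Med"]

    def test_all_low_gives_empty(self):
        df = _trains_df(
            [("S", pd.Timestamp("2015-01-01"), np.full(4, 30e3), "Low")] * 3
        )
        assert detection.filter_trains(df).empty

    def test_empty_input_gives_empty(self):
        assert detection.filter_trains(_trains_df([])).empty

    def test_unknown_label_rejected_and_counted(self):
        df = _trains_df(
            [
                ("S", pd.Timestamp("2015-01-01"), np.full(4, 30e3), "Hi"),
                ("S", pd.Timestamp("2015-01-01"), np.full(4, 30e3), "???"),
            ]
        )
        out = detection.filter_trains(df)
        assert len(out) == 1
        assert out.attrs["n_unknown_quality"] == 1


class TestBinHourly:
    def _effort(self, start, end):
        return pd.DataFrame(
            [("S", pd.Timestamp(start), pd.Timestamp(end))],
            columns=["site", "start", "end"],
        )

    def test_train_spanning_two_minutes(self):
        # 10:05:30 + 40 s of clicking ends 10:06:10: minutes 5 and 6
        df = _trains_df(
            [("S", pd.Timestamp("2015-01-01 10:05:30"), np.full(100, 400_000.0), "Hi")]
        )
        hours = detection.bin_hourly(df, self._effort("2015-01-01 10:00", "2015-01-01 11:00"))
        assert hours.loc[0, "minutes_detected"] == 2

    def test_effort_ending_midhour_marks_incomplete(self):
        df = _trains_df([])
        hours = detection.bin_hourly(df, self._effort("2015-01-01 10:00", "2015-01-01 10:30"))
        assert len(hours) == 1
        assert not hours.loc[0, "complete"]

    def test_two_trains_in_same_minute_count_once(self):
        rows = [
            ("S", pd.Timestamp("2015-01-01 10:07:01"), np.full(4, 250_000.0), "Hi"),
            ("S", pd.Timestamp("2015-01-01 10:07:40"), np.full(4, 250_000.0), "Med"),
        ]
        hours = detection.bin_hourly(
            _trains_df(rows), self._effort("2015-01-01 10:00", "2015-01-01 11:00")
        )
        assert hours.loc[0, "minutes_detected"] == 1

    def test_train_ending_on_boundary_stays_in_earlier_unit(self):
        # spans 10:59:30 to exactly 11:00:00 under the half-open convention
        rows = [("S", pd.Timestamp("2015-01-01 10:59:30"), np.full(30, 1_000_000.0), "Hi")]
        hours = detection.bin_hourly(
            _trains_df(rows), self._effort("2015-01-01 10:00", "2015-01-01 12:00")
        )
        by_hour = hours.set_index(hours["hour_start"].dt.hour)["minutes_detected"]
        assert by_hour[10] == 1
        assert by_hour[11] == 0

    def test_train_outside_effort_raises(self):
        rows = [("S", pd.Timestamp("2015-01-02 10:00:05"), np.full(4, 250_000.0), "Hi")]
        with pytest.raises(ValueError, match="outside recording effort"):
            detection.bin_hourly(
                _trains_df(rows), self._effort("2015-01-01 00:00", "2015-01-02 00:00")
            )

    def test_order_invariance(self, small_trains, small_effort):
        filtered = detection.filter_trains(small_trains)
        shuffled = filtered.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = detection.bin_hourly(filtered, small_effort)
        b = detection.bin_hourly(shuffled, small_effort)
        pd.testing.assert_frame_equal(a, b)


class TestPphAndMonthly:
    def test_pph_flag_threshold(self):
        hours = pd.DataFrame(
            {"minutes_detected": [0, 1, 43], "complete": [True] * 3}
        )
        assert list(detection.pph_flags(hours)) == [False, True, True]

    def test_monthly_arithmetic_on_three_days(self):
        rows = []
        # day 1: 2 PPH, day 2: 0, day 3: 5
        for day, n_pos in [(1, 2), (2, 0), (3, 5)]:
            for h in range(24):
                rows.append(
                    ("S", pd.Timestamp(2015, 3, day, h), 1 if h < n_pos else 0, True)
                )
        hours = pd.DataFrame(rows, columns=["site", "hour_start", "minutes_detected", "complete"])
        m = detection.monthly_metrics(hours)
        assert len(m) == 1
        row = m.iloc[0]
        assert row["median_pph"] == 2.0
        assert row["total_pph"] == 7
        assert row["max_pph"] == 5
        assert row["proportion_days"] == pytest.approx(2 / 3)
        assert row["n_recording_days"] == 3

    def test_saturated_month_hits_ceiling(self):
        rows = [
            ("S", pd.Timestamp(2015, 4, d, h), 10, True)
            for d in range(1, 31)
            for h in range(24)
        ]
        hours = pd.DataFrame(rows, columns=["site", "hour_start", "minutes_detected", "complete"])
        m = detection.monthly_metrics(hours)
        assert m.iloc[0]["total_pph"] == 720
        assert m.iloc[0]["total_pph"] <= 24 * m.iloc[0]["n_recording_days"]

    def test_sum_of_monthly_totals_equals_global_pph(self, small_hours):
        complete = small_hours[small_hours["complete"]]
        m = detection.monthly_metrics(small_hours)
        assert m["total_pph"].sum() == int((complete["minutes_detected"] >= 1).sum())


class TestIsoWeek:
    @pytest.mark.parametrize(
        "date,expected",
        [
            (dt.date(2016, 1, 1), (2015, 53)),  # a Friday in the prior ISO year
            (dt.date(2015, 1, 5), (2015, 2)),
            (dt.date(2015, 12, 28), (2015, 53)),
        ],
    )
    def test_calendar_oracle_values(self, date, expected):
        assert detection.iso_week(date) == expected

    def test_constant_within_week(self):
        monday = dt.date(2015, 6, 8)
        assert monday.weekday() == 0
        assert detection.iso_week(monday) == detection.iso_week(monday + dt.timedelta(days=6))


class TestWeeklyOccurrence:
    def _hours(self, n, n_pos, start="2015-06-08"):
        ts = pd.date_range(start, periods=n, freq="h")
        return pd.DataFrame(
            {
                "site": "S",
                "hour_start": ts,
                "minutes_detected": [1] * n_pos + [0] * (n - n_pos),
                "complete": True,
            }
        )

    def test_full_week_proportion(self):
        w = detection.weekly_occurrence(self._hours(168, 42))
        assert len(w) == 1
        assert w.iloc[0]["proportion_hours_present"] == pytest.approx(0.25)
        assert w.iloc[0]["n_complete_hours"] == 168

    def test_partial_week(self):
        w = detection.weekly_occurrence(self._hours(24, 6))
        assert w.iloc[0]["proportion_hours_present"] == pytest.approx(0.25)
        assert w.iloc[0]["n_complete_hours"] == 24

    def test_zero_positive(self):
        w = detection.weekly_occurrence(self._hours(168, 0))
        assert w.iloc[0]["proportion_hours_present"] == 0.0


class TestRoundTrip:
    def test_minutes_match_simulator_truth(self, small_truth, small_hours):
        merged = small_hours.merge(small_truth.hours, on=["site", "hour_start"])
        both = merged[merged["complete"] & merged["in_effort"]]
        assert len(both) > 1000
        assert (both["minutes_detected"] == both["minutes"]).all()

    def test_csv_round_trip_preserves_trains(self, small_trains, tmp_path):
        path = tmp_path / "trains.csv"
        detection.write_trains_csv(small_trains, path)
        back = detection.read_trains_csv(path)
        assert len(back) == len(small_trains)
        assert (back["quality"] == small_trains["quality"]).all()
        assert (back["start"] == small_trains["start"]).all()
        np.testing.assert_allclose(
            np.concatenate(list(back["icis"])),
            np.concatenate(list(small_trains["icis"])),
        )
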