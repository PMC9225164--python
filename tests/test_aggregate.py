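"""Zero filtering, HR interval statistics, and the day/week/period chain."""

import numpy as np
import pandas as pd
import pytest

from wearva import (
    BEHAVIOR_VARIABLES, Cohort, aggregate_day, aggregate_period, aggregate_week,
    day_aggregates, filter_zero_measurements, interval_hr_stats,
)

from .conftest import make_intervals


def _hr_frame(pid, minutes, bpms):
    return pd.DataFrame({"patient_id": pid, "minute": pd.to_datetime(minutes),
                         "bpm": np.asarray(bpms, dtype=float)})


def _sleep_frame(pid, minutes, classes):
    return pd.DataFrame({"patient_id": pid, "minute": pd.to_datetime(minutes),
                         "sleep_class": classes})


class TestZeroFilter:
    def test_zero_bpm_minutes_removed(self):
        c = Cohort.empty()
        c.hr = _hr_frame("p1", ["2017-03-01T09:00", "2017-03-01T09:01", "2017-03-01T09:02"],
                         [0, 60, 62])
        out = filter_zero_measurements(c)
        assert list(out.hr["bpm"]) == [60, 62]

    def test_zero_steps_with_class_retained_without_class_removed(self):
        c = Cohort.empty()
        c.intervals = pd.concat([
            make_intervals("p1", "2017-03-01", [9.0], klass="light", steps=0),
            make_intervals("p1", "2017-03-01", [9.25], klass="missing", steps=0),
            make_intervals("p1", "2017-03-01", [9.5], klass="missing", steps=50),
        ], ignore_index=True)
        out = filter_zero_measurements(c)
        assert len(out.intervals) == 2  # classified zero + step-carrying missing survive
        assert set(out.intervals["activity_class"]) == {"light", "missing"}
        assert 0 in set(out.intervals["steps"])


class TestIntervalHRStats:
    def test_small_example(self):
        s = interval_hr_stats([60, 62, 64])
        assert (s.min, s.mean, s.median, s.max, s.sd) == (60, 62, 62, 64, 2.0)

    def test_single_value_degenerate(self):
        s = interval_hr_stats([70])
        assert s == (70, 70, 70, 70, 0.0)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(45, 150, size=15)
        s = interval_hr_stats(v)
        assert s.min == v.min() and s.max == v.max()
        assert np.isclose(s.mean, sum(v) / 15)
        assert np.isclose(s.median, sorted(v)[7])
        assert np.isclose(s.sd, np.sqrt(sum((x - v.mean()) ** 2 for x in v) / 14))

    def test_empty_interval_is_an_error(self):
        with pytest.raises(ValueError):
            interval_hr_stats([])


class TestAggregateDay:
    def test_intensity_durations_and_combinations(self):
        iv = pd.concat([
            make_intervals("p1", "2017-03-01", [9.0, 9.25], klass="light"),
            make_intervals("p1", "2017-03-01", [9.5], klass="fair"),
        ], ignore_index=True)
        day = aggregate_day(iv)
        assert day["Light"] == 30 and day["Fair"] == 15
        assert day["Light+Fair"] == 45 and day["Active"] == 45 and day["Vig"] == 0

    def test_steps_sum(self):
        iv = make_intervals("p1", "2017-03-01", [9.0, 9.25, 9.5], steps=0)
        iv["steps"] = [100, 200, 300]
        assert aggregate_day(iv)["Steps"] == 600

    def test_sleep_minutes_and_cumulative_sleep(self):
        minutes = pd.date_range("2017-03-01T01:00", periods=100, freq="min")
        sl = _sleep_frame("p1", minutes, ["asleep"] * 90 + ["restless"] * 10)
        day = aggregate_day(make_intervals("p1", "2017-03-01", [9.0]), sleep=sl)
        assert day["Asleep"] == 90 and day["Restless"] == 10
        assert day["Asleep+Restless"] == 100 and day["Sleep"] == 100

    def test_unknown_minutes_count_only_in_cumulative_sleep(self):
        minutes = pd.date_range("2017-03-01T01:00", periods=10, freq="min")
        sl = _sleep_frame("p1", minutes, ["asleep"] * 6 + ["unknown"] * 4)
        day = aggregate_day(make_intervals("p1", "2017-03-01", [9.0]), sleep=sl)
        assert day["Asleep"] == 6 and day["Sleep"] == 10
        assert day["Asleep+Awake"] == 6  # unknown contributes nowhere else

    def test_daily_hr_composition_across_intervals(self):
        hr = _hr_frame("p1",
                       ["2017-03-01T09:00", "2017-03-01T09:01",
                        "2017-03-01T10:00", "2017-03-01T10:01"],
                       [60, 64, 80, 90])
        day = aggregate_day(make_intervals("p1", "2017-03-01", [9.0]), hr=hr)
        assert day["MinHR"] == 60 and day["MaxHR"] == 90
        assert np.isclose(day["MeanHR"], (62 + 85) / 2)
        assert np.isclose(day["SDHR"], (np.std([60, 64], ddof=1) + np.std([80, 90], ddof=1)) / 2)

    def test_vectorised_table_matches_direct_aggregation(self, small_cohort, small_day_table):
        work = filter_zero_measurements(small_cohort)
        for pid, date in [small_day_table.index[0], small_day_table.index[-1]]:
            iv = work.intervals[(work.intervals["patient_id"] == pid)
                                & (work.intervals["start"].dt.normalize() == date)]
            sl = work.sleep[(work.sleep["patient_id"] == pid)
                            & (work.sleep["minute"].dt.normalize() == date)]
            hr = work.hr[(work.hr["patient_id"] == pid)
                         & (work.hr["minute"].dt.normalize() == date)]
            direct = aggregate_day(iv, sleep=sl, hr=hr)
            row = small_day_table.loc[(pid, date)]
            for var in BEHAVIOR_VARIABLES:
                if np.isnan(direct[var]):
                    assert np.isnan(row[var])
                else:
                    assert np.isclose(direct[var], row[var]), var


class TestWeekPeriod:
    def test_weekly_mean_of_daily_values(self):
        days = pd.DataFrame({"Steps": [6000.0, 8000.0]})
        assert aggregate_week(days)["Steps"] == 7000

    def test_single_constituent_identity(self):
        one = pd.DataFrame({"Steps": [4200.0], "MinHR": [51.0]})
        assert aggregate_week(one).equals(one.iloc[0])
        assert aggregate_period(one).equals(one.iloc[0])

    def test_period_mean_of_weekly_values(self):
        weeks = pd.DataFrame({"MinHR": [50.0, 54.0]})
        assert aggregate_period(weeks)["MinHR"] == 52

    def test_random_values_match_brute_force(self):
        rng = np.random.default_rng(11)
        days = pd.DataFrame(rng.uniform(0, 500, size=(7, 3)), columns=["Steps", "Light", "MinHR"])
        wk = aggregate_week(days)
        for col in days:
            assert np.isclose(wk[col], sum(days[col]) / 7)
        weeks = pd.DataFrame(rng.uniform(0, 500, size=(8, 3)), columns=days.columns)
        pe = aggregate_period(weeks)
        for col in weeks:
            assert np.isclose(pe[col], sum(weeks[col]) / 8)

    def test_identical_weeks_do_not_drift(self):
        weeks = pd.DataFrame({"Light": [123.0] * 8, "Steps": [4567.0] * 8})
        pe = aggregate_period(weeks)
        assert pe["Light"] == 123.0 and pe["Steps"] == 4567.0

    def test_running_minimum_switch_for_min_hr(self):
        days = pd.DataFrame({"MinHR": [50.0, 58.0], "MeanHR": [70.0, 74.0]})
        default = aggregate_week(days)
        running = aggregate_week(days, weekly_minhr="min")
        assert default["MinHR"] == 54.0 and running["MinHR"] == 50.0
        assert default["MeanHR"] == running["MeanHR"] == 72.0

    def test_zero_constituents_is_an_error(self):
        with pytest.raises(ValueError, match="zero valid"):
            aggregate_week(pd.DataFrame({"Steps": []}))


class TestPipelineInvariants:
    def test_conservation_identities_hold_exactly_on_every_synthetic_day(self, small_day_table):
        t = small_day_table
        assert (t["Light+Fair"] == t["Light"] + t["Fair"]).all()
        assert (t["Fair+Vig"] == t["Fair"] + t["Vig"]).all()
        assert (t["Active"] == t["Light"] + t["Fair"] + t["Vig"]).all()
        sleep_days = t.dropna(subset=["Sleep"])
        assert (sleep_days["Asleep+Awake"] == sleep_days["Asleep"] + sleep_days["Awake"]).all()
        assert (sleep_days["Sleep"] >= sleep_days["Asleep"] + sleep_days["Awake"]
                + sleep_days["Restless"]).all()

    def test_daily_hr_ordering(self, small_day_table):
        hr_days = small_day_table.dropna(subset=["MinHR"])
        assert (hr_days["MinHR"] <= hr_days["MeanHR"] + 1e-12).all()
        assert (hr_days["MeanHR"] <= hr_days["MaxHR"] + 1e-12).all()

    def test_record_order_does_not_change_aggregates(self, small_cohort, small_day_table):
        work = filter_zero_measurements(small_cohort)
        rng = np.random.default_rng(0)
        shuffled = Cohort(
            intervals=work.intervals.sample(frac=1, random_state=1).reset_index(drop=True),
            sleep=work.sleep.sample(frac=1, random_state=2).reset_index(drop=True),
            hr=work.hr.sample(frac=1, random_state=3).reset_index(drop=True),
            events=work.events, calendar=work.calendar)
        pd.testing.assert_frame_equal(day_aggregates(shuffled), small_day_table)
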