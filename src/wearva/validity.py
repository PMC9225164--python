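"""Day / week / period data-validity scenarios.

Wearable data are only informative where the device was actually worn, so
every downstream aggregate is computed under an explicit data-availability
scenario with three knobs:

* a day is valid when at least ``day_min_hours`` hours of classified
  15-minute activity intervals (any class, sedentary included — the
  criterion is about data availability) start between 8 a.m. and 8 p.m.;
* a week (7 consecutive days) is valid when it contains at least
  ``week_min_valid_days`` valid days;
* a period of ``w`` weeks (1-8) is valid when the fraction of valid weeks
  is at least ``period_min_valid_fraction``.

The knob values are drawn from closed sets — {1, 2, 4, 8} hours,
{4, 5, 7} days, {50%, 75%, 100%} — giving the 4 x 3 x 3 = 36 scenario
combinations enumerated by :func:`enumerate_scenarios`.  Relaxing any knob
can only turn invalid units valid (monotonicity), and validity composes:
a week depends only on its days, a period only on its weeks.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAY_MIN_HOURS = (1, 2, 4, 8)
WEEK_MIN_VALID_DAYS = (4, 5, 7)
PERIOD_MIN_VALID_FRACTIONS = (0.50, 0.75, 1.00)

#: clock window, half-open on interval start times
DAY_WINDOW_START_HOUR = 8
DAY_WINDOW_END_HOUR = 20

MAX_PERIOD_WEEKS = 8


@dataclass(frozen=True, order=True)
class ValidityScenario:
    """One of the 36 (day-hours, week-days, period-fraction) combinations."""

    day_min_hours: int
    week_min_valid_days: int
    period_min_valid_fraction: float

    def __post_init__(self):
        if self.day_min_hours not in DAY_MIN_HOURS:
            raise ValueError(f"day_min_hours must be one of {DAY_MIN_HOURS}")
        if self.week_min_valid_days not in WEEK_MIN_VALID_DAYS:
            raise ValueError(f"week_min_valid_days must be one of {WEEK_MIN_VALID_DAYS}")
        if self.period_min_valid_fraction not in PERIOD_MIN_VALID_FRACTIONS:
            raise ValueError(f"period_min_valid_fraction must be one of {PERIOD_MIN_VALID_FRACTIONS}")

    @property
    def label(self) -> str:
        return (f"{self.day_min_hours}h-{self.week_min_valid_days}d-"
                f"{int(round(self.period_min_valid_fraction * 100))}%")

    @classmethod
    def parse(cls, text: str) -> "ValidityScenario":
        """Parse ``"DAY,WEEK,FRAC"`` (e.g. ``"4,5,0.75"``)."""
        day, week, frac = (t.strip() for t in text.split(","))
        return cls(int(day), int(week), float(frac))


def enumerate_scenarios() -> list[ValidityScenario]:
    """All 36 scenarios in (day, week, period) lexicographic order."""
    return [ValidityScenario(d, w, f)
            for d, w, f in product(DAY_MIN_HOURS, WEEK_MIN_VALID_DAYS, PERIOD_MIN_VALID_FRACTIONS)]


def count_window_intervals(day_intervals: pd.DataFrame) -> int:
    """Classified 15-min intervals starting in [08:00, 20:00) on one patient-date."""
    if not len(day_intervals):
        return 0
    hours = day_intervals["start"].dt.hour
    classified = day_intervals["activity_class"] != "missing"
    in_window = (hours >= DAY_WINDOW_START_HOUR) & (hours < DAY_WINDOW_END_HOUR)
    return int((classified & in_window).sum())


def is_valid_day(day_intervals: pd.DataFrame, scenario: ValidityScenario) -> bool:
    """True iff the patient-date has >= 4 x day_min_hours classified intervals
    starting between 8 a.m. and 8 p.m. (1 hour = four 15-minute intervals)."""
    return count_window_intervals(day_intervals) >= 4 * scenario.day_min_hours


def is_valid_week(week_days: Sequence[bool], scenario: ValidityScenario) -> bool:
    """True iff at least ``week_min_valid_days`` of the 7 day flags are valid."""
    flags = list(week_days)
    if len(flags) != 7:
        raise ValueError(f"a week has exactly 7 days, got {len(flags)}")
    return sum(bool(f) for f in flags) >= scenario.week_min_valid_days


def is_valid_period(period_weeks: Sequence[bool], scenario: ValidityScenario) -> bool:
    """True iff the valid-week fraction is >= the scenario threshold.

    The comparison is exact on the rational count/w — 3/4 passes 0.75,
    2/3 fails 0.75 — with no rounding.
    """
    flags = list(period_weeks)
    w = len(flags)
    if not 1 <= w <= MAX_PERIOD_WEEKS:
        raise ValueError(f"period length must be 1..{MAX_PERIOD_WEEKS} weeks, got {w}")
    count = sum(bool(f) for f in flags)
    return Fraction(count, w) >= Fraction(scenario.period_min_valid_fraction)


def day_validity_table(intervals: pd.DataFrame, day_min_hours: int) -> pd.DataFrame:
    """Vectorised per-(patient, date) window-interval counts and validity.

    Returns a frame with columns ``patient_id, date, n_window_intervals,
    valid_day``; dates with no interval records do not appear (they are
    invalid under every scenario).
    """
    if not len(intervals):
        return pd.DataFrame(columns=["patient_id", "date", "n_window_intervals", "valid_day"])
    hours = intervals["start"].dt.hour
    ok = ((intervals["activity_class"] != "missing")
          & (hours >= DAY_WINDOW_START_HOUR) & (hours < DAY_WINDOW_END_HOUR))
    counts = (intervals.assign(_ok=ok.astype(np.int64), date=intervals["start"].dt.normalize())
              .groupby(["patient_id", "date"], observed=True)["_ok"].sum()
              .rename("n_window_intervals").reset_index())
    counts["valid_day"] = counts["n_window_intervals"] >= 4 * day_min_hours
    return counts


def validity_report(intervals: pd.DataFrame,
                    scenarios: Iterable[ValidityScenario]) -> pd.DataFrame:
    """Per-patient-day validity under each scenario (long format).

    Week/period validity is window-relative in this pipeline (weeks are
    anchored to the exposure window, not the calendar), so the audit table
    reports the day level, which is scenario-dependent but window-free.
    """
    out = []
    for sc in scenarios:
        tab = day_validity_table(intervals, sc.day_min_hours)
        tab.insert(0, "scenario", sc.label)
        out.append(tab)
    if not out:
        return pd.DataFrame(columns=["scenario", "patient_id", "date", "n_window_intervals", "valid_day"])
    return pd.concat(out, ignore_index=True)
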