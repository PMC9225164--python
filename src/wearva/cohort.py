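"""Domain types and CSV I/O for wearable streams, VA events, and monitoring calendars.

A cohort bundles five record collections:

* 15-minute activity intervals (steps + intensity class),
* 1-minute sleep-class minutes,
* 1-minute heart-rate minutes,
* ventricular-arrhythmia (VA) event days reported by the implanted ICD,
* a per-patient monitoring calendar (first and last monitored day).

All tables are plain :class:`pandas.DataFrame` objects with fixed schemas;
:class:`Cohort` adds validation of the closed class sets, the 15-minute grid,
per-day record-count ceilings (96 intervals, 1440 minutes), and calendar
containment of event dates.  Timestamps are ISO-8601, timezone-naive, and
interpreted as local clock time: every day-boundary rule in the pipeline
(e.g. the 8 a.m.-8 p.m. validity window) is clock-local.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

ACTIVITY_CLASSES = ("sedentary", "light", "fair", "vigorous", "missing")
SLEEP_CLASSES = ("asleep", "awake", "restless", "unknown")
EVENT_TYPES = ("VT", "VT1", "VT2", "VF-VT")

MAX_INTERVALS_PER_DAY = 96
MAX_MINUTES_PER_DAY = 1440

INTERVAL_COLUMNS = ("patient_id", "start", "steps", "activity_class")
SLEEP_COLUMNS = ("patient_id", "minute", "sleep_class")
HR_COLUMNS = ("patient_id", "minute", "bpm")
EVENT_COLUMNS = ("patient_id", "date", "event_type")
CALENDAR_COLUMNS = ("patient_id", "first_day", "last_day")

#: canonical file names used by :func:`read_cohort` / :func:`write_cohort`
FILE_NAMES = {
    "intervals": "intervals.csv",
    "sleep": "sleep.csv",
    "hr": "hr.csv",
    "events": "events.csv",
    "calendar": "calendar.csv",
}


class CohortValidationError(ValueError):
    """A record collection violates a structural invariant."""


class CohortParseError(ValueError):
    """A CSV field could not be parsed; the message names file and line."""


@dataclass
class Cohort:
    """The five record collections of one study cohort.

    Attributes
    ----------
    intervals
        columns ``patient_id, start, steps, activity_class``; ``start`` on a
        15-minute grid, ``activity_class`` in :data:`ACTIVITY_CLASSES`
        (``missing`` marks a non-worn interval row, if materialised at all).
    sleep
        columns ``patient_id, minute, sleep_class``.
    hr
        columns ``patient_id, minute, bpm``.
    events
        columns ``patient_id, date, event_type``; daily granularity — the ICD
        outcome used downstream is "VA on this day, yes/no".
    calendar
        columns ``patient_id, first_day, last_day``; defines the monitoring
        days that serve as index days in the case-crossover construction.
    """

    intervals: pd.DataFrame
    sleep: pd.DataFrame
    hr: pd.DataFrame
    events: pd.DataFrame
    calendar: pd.DataFrame

    @classmethod
    def empty(cls) -> "Cohort":
        return cls(
            intervals=pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                                    zip(INTERVAL_COLUMNS, ("str", "datetime64[ns]", "int64", "str"))}),
            sleep=pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                                zip(SLEEP_COLUMNS, ("str", "datetime64[ns]", "str"))}),
            hr=pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             zip(HR_COLUMNS, ("str", "datetime64[ns]", "float64"))}),
            events=pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                                 zip(EVENT_COLUMNS, ("str", "datetime64[ns]", "str"))}),
            calendar=pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                                   zip(CALENDAR_COLUMNS, ("str", "datetime64[ns]", "datetime64[ns]"))}),
        )

    def copy(self) -> "Cohort":
        return Cohort(**{f.name: getattr(self, f.name).copy() for f in fields(self)})

    def sort(self) -> "Cohort":
        """Return a copy sorted by (patient_id, time) with a fresh index."""
        return Cohort(
            intervals=self.intervals.sort_values(["patient_id", "start"], kind="mergesort").reset_index(drop=True),
            sleep=self.sleep.sort_values(["patient_id", "minute"], kind="mergesort").reset_index(drop=True),
            hr=self.hr.sort_values(["patient_id", "minute"], kind="mergesort").reset_index(drop=True),
            events=self.events.sort_values(["patient_id", "date", "event_type"], kind="mergesort").reset_index(drop=True),
            calendar=self.calendar.sort_values("patient_id", kind="mergesort").reset_index(drop=True),
        )

    # -- validation -------------------------------------------------------

    def validate(self) -> "Cohort":
        """Check all structural invariants; raise :class:`CohortValidationError`.

        Violated input is rejected, never silently truncated.
        """
        _check_columns(self.intervals, INTERVAL_COLUMNS, "intervals")
        _check_columns(self.sleep, SLEEP_COLUMNS, "sleep")
        _check_columns(self.hr, HR_COLUMNS, "hr")
        _check_columns(self.events, EVENT_COLUMNS, "events")
        _check_columns(self.calendar, CALENDAR_COLUMNS, "calendar")

        iv = self.intervals
        if len(iv):
            bad = ~iv["activity_class"].isin(ACTIVITY_CLASSES)
            if bad.any():
                raise CohortValidationError(
                    f"unknown activity_class values: {sorted(iv.loc[bad, 'activity_class'].unique())}")
            if (iv["steps"] < 0).any():
                raise CohortValidationError("negative step counts in intervals")
            off_grid = (iv["start"].dt.minute % 15 != 0) | (iv["start"].dt.second != 0)
            if off_grid.any():
                raise CohortValidationError("interval start not aligned to the 15-minute grid")
            _check_duplicates(iv, ["patient_id", "start"], "intervals")
            _check_day_ceiling(iv, "start", MAX_INTERVALS_PER_DAY, "intervals")

        if len(self.sleep):
            bad = ~self.sleep["sleep_class"].isin(SLEEP_CLASSES)
            if bad.any():
                raise CohortValidationError(
                    f"unknown sleep_class values: {sorted(self.sleep.loc[bad, 'sleep_class'].unique())}")
            _check_duplicates(self.sleep, ["patient_id", "minute"], "sleep")
            _check_day_ceiling(self.sleep, "minute", MAX_MINUTES_PER_DAY, "sleep")

        if len(self.hr):
            if (self.hr["bpm"] < 0).any():
                raise CohortValidationError("negative bpm in heart-rate minutes")
            _check_duplicates(self.hr, ["patient_id", "minute"], "hr")
            _check_day_ceiling(self.hr, "minute", MAX_MINUTES_PER_DAY, "hr")

        if len(self.calendar):
            _check_duplicates(self.calendar, ["patient_id"], "calendar")
            if (self.calendar["first_day"] > self.calendar["last_day"]).any():
                raise CohortValidationError("calendar with first_day after last_day")

        ev = self.events
        if len(ev):
            bad = ~ev["event_type"].isin(EVENT_TYPES)
            if bad.any():
                raise CohortValidationError(
                    f"event_type outside {EVENT_TYPES}: {sorted(ev.loc[bad, 'event_type'].unique())}")
            cal = self.calendar.set_index("patient_id")
            missing = set(ev["patient_id"]) - set(cal.index)
            if missing:
                raise CohortValidationError(f"events for patients absent from calendar: {sorted(missing)}")
            first = cal["first_day"].reindex(ev["patient_id"]).to_numpy()
            last = cal["last_day"].reindex(ev["patient_id"]).to_numpy()
            d = ev["date"].to_numpy()
            if ((d < first) | (d > last)).any():
                raise CohortValidationError("event date outside the patient's monitoring span")
        return self


def _check_columns(df: pd.DataFrame, expected: tuple, name: str) -> None:
    if tuple(df.columns) != expected:
        raise CohortValidationError(f"{name}: expected columns {expected}, got {tuple(df.columns)}")


def _check_duplicates(df: pd.DataFrame, keys: list, name: str) -> None:
    dup = df.duplicated(keys)
    if dup.any():
        row = df[dup].iloc[0]
        raise CohortValidationError(f"{name}: duplicate records for {tuple(row[k] for k in keys)}")


def _check_day_ceiling(df: pd.DataFrame, time_col: str, ceiling: int, name: str) -> None:
    counts = df.groupby([df["patient_id"], df[time_col].dt.normalize()], observed=True).size()
    if (counts > ceiling).any():
        key = counts.idxmax()
        raise CohortValidationError(
            f"{name}: {counts.max()} records on patient-day {key} exceed the ceiling of {ceiling}")


# -- CSV I/O --------------------------------------------------------------


def _paths(directory_or_paths) -> dict:
    if isinstance(directory_or_paths, (str, os.PathLike)):
        return {k: os.path.join(directory_or_paths, v) for k, v in FILE_NAMES.items()}
    return dict(directory_or_paths)


def _parse_times(df: pd.DataFrame, col: str, path: str) -> pd.DataFrame:
    parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2  # header is line 1
        raise CohortParseError(f"{path}:{line}: malformed timestamp {df[col].iloc[line - 2]!r}")
    df[col] = parsed
    return df


def read_cohort(directory_or_paths) -> Cohort:
    """Read the five cohort CSVs, parse, type, sort, and validate.

    Parameters
    ----------
    directory_or_paths
        Either a directory containing the canonical :data:`FILE_NAMES`, or a
        mapping ``{"intervals": path, "sleep": path, ...}``.

    Raises
    ------
    CohortParseError
        malformed timestamp (message names file and line).
    CohortValidationError
        class outside its closed set, duplicate timestamps, day-count
        ceilings exceeded, events outside the monitoring span.
    """
    p = _paths(directory_or_paths)
    intervals = pd.read_csv(p["intervals"], dtype={"patient_id": str, "activity_class": str, "steps": "int64"})
    sleep = pd.read_csv(p["sleep"], dtype={"patient_id": str, "sleep_class": str})
    hr = pd.read_csv(p["hr"], dtype={"patient_id": str, "bpm": "float64"})
    events = pd.read_csv(p["events"], dtype={"patient_id": str, "event_type": str})
    calendar = pd.read_csv(p["calendar"], dtype={"patient_id": str})

    intervals = _parse_times(intervals, "start", p["intervals"])
    sleep = _parse_times(sleep, "minute", p["sleep"])
    hr = _parse_times(hr, "minute", p["hr"])
    events = _parse_times(events, "date", p["events"])
    calendar = _parse_times(calendar, "first_day", p["calendar"])
    calendar = _parse_times(calendar, "last_day", p["calendar"])

    cohort = Cohort(intervals=intervals, sleep=sleep, hr=hr, events=events, calendar=calendar).sort()
    return cohort.validate()


def write_cohort(cohort: Cohort, directory_or_paths) -> dict:
    """Write the cohort to CSV so that :func:`read_cohort` round-trips exactly.

    Returns the mapping of written paths.
    """
    p = _paths(directory_or_paths)
    for path in p.values():
        parent = os.path.dirname(path)
        if parent:
            os.makedirs(parent, exist_ok=True)
    c = cohort.sort()
    c.intervals.assign(start=c.intervals["start"].dt.strftime("%Y-%m-%dT%H:%M:%S")).to_csv(p["intervals"], index=False)
    c.sleep.assign(minute=c.sleep["minute"].dt.strftime("%Y-%m-%dT%H:%M:%S")).to_csv(p["sleep"], index=False)
    c.hr.assign(minute=c.hr["minute"].dt.strftime("%Y-%m-%dT%H:%M:%S")).to_csv(p["hr"], index=False)
    c.events.assign(date=c.events["date"].dt.strftime("%Y-%m-%d")).to_csv(p["events"], index=False)
    c.calendar.assign(
        first_day=c.calendar["first_day"].dt.strftime("%Y-%m-%d"),
        last_day=c.calendar["last_day"].dt.strftime("%Y-%m-%d"),
    ).to_csv(p["calendar"], index=False)
    return p
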