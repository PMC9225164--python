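"""Zero-measurement filtering and day -> week -> period behavior aggregation.

The wearable reports three streams at two resolutions: step counts and an
intensity class per 15-minute interval, sleep classes per minute, and heart
rate per minute.  This module turns them into the analysis variables:

===========  ======================================================  =====
variable     definition                                              unit
===========  ======================================================  =====
Steps        sum of interval step counts                             count
Light        15 x count of light intervals                           min
Fair         15 x count of fair intervals                            min
Vig          15 x count of vigorous intervals                        min
Light+Fair   Light + Fair                                            min
Fair+Vig     Fair + Vig                                              min
Active       Light + Fair + Vig                                      min
Asleep /     count of sleep minutes of that class (plus the           min
Awake /      pairwise sums, and Sleep = all sleep minutes
Restless     including 'unknown')
MinHR ...    daily min/mean/median/max of the per-interval HR         bpm
SDHR         statistics; SDHR = mean of per-interval sample SDs
===========  ======================================================  =====

Sedentary durations (and any combination containing them) are excluded:
the tracker cannot distinguish sedentary wear from sleep or non-wear, so
those durations are unreliable.  'Unknown' sleep minutes contribute only to
the cumulative Sleep variable, never on their own.

Zero filtering removes measurements reported as 0 — heart-rate minutes with
``bpm == 0`` and interval rows carrying no measurement at all (zero steps
and no intensity class).  A zero step count inside a classified interval is
a real measurement and is retained.  Weekly and period aggregates are
arithmetic means over the *valid* constituent units only; by default all
five daily HR statistics are averaged upward (a ``weekly_minhr="min"``
switch takes the running minimum of MinHR instead).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort

ACTIVITY_VARIABLES = ("Steps", "Light", "Light+Fair", "Fair", "Fair+Vig", "Vig", "Active")
SLEEP_VARIABLES = ("Asleep", "Awake", "Restless", "Asleep+Awake",
                   "Asleep+Restless", "Awake+Restless", "Sleep")
HR_VARIABLES = ("MinHR", "MeanHR", "MedianHR", "MaxHR", "SDHR")
BEHAVIOR_VARIABLES = ACTIVITY_VARIABLES + SLEEP_VARIABLES + HR_VARIABLES

#: unreliable because sedentary duration conflates wear, sleep, and non-wear
EXCLUDED_VARIABLES = ("Sedentary", "Sedentary+Light", "Unknown")

UNITS = {v: "minutes" for v in ACTIVITY_VARIABLES + SLEEP_VARIABLES}
UNITS["Steps"] = "count"
UNITS.update({v: "bpm" for v in HR_VARIABLES})


class IntervalHRStats(NamedTuple):
    """Five heart-rate statistics of the 1-min values inside one 15-min interval."""

    min: float
    mean: float
    median: float
    max: float
    sd: float


def filter_zero_measurements(cohort: Cohort) -> Cohort:
    """Drop measurements reported as '0'.

    * heart-rate minutes with ``bpm == 0`` are removed;
    * interval rows with ``steps == 0`` *and* a missing activity class are
      removed (the row carries no measurement);
    * ``steps == 0`` inside a classified interval is kept — the intensity
      class is a real measurement and the zero count is informative.
    """
    iv = cohort.intervals
    drop = (iv["steps"] == 0) & (iv["activity_class"] == "missing")
    # boolean indexing already copies; the untouched frames are shared and
    # treated as immutable throughout the pipeline
    return Cohort(
        intervals=iv[~drop].reset_index(drop=True),
        sleep=cohort.sleep,
        hr=cohort.hr[cohort.hr["bpm"] != 0].reset_index(drop=True),
        events=cohort.events,
        calendar=cohort.calendar,
    )


def interval_hr_stats(bpm_values: Sequence[float], start=None) -> IntervalHRStats:
    """Min / mean / median / max / sample SD of the 1-min values in one interval.

    ``sd`` uses the n-1 denominator and is 0 for a single value.  Empty
    input is a caller error: intervals without heart-rate minutes emit no
    statistics at all.
    """
    v = np.asarray(bpm_values, dtype=float)
    if v.size == 0:
        raise ValueError("interval_hr_stats requires at least one 1-min value")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return IntervalHRStats(float(v.min()), float(v.mean()), float(np.median(v)), float(v.max()), sd)


def _activity_day_table(intervals: pd.DataFrame) -> pd.DataFrame:
    date = intervals["start"].dt.normalize()
    g = intervals.assign(date=date).groupby(["patient_id", "date"], observed=True)
    steps = g["steps"].sum().rename("Steps")
    cls = (intervals.assign(date=date)
           .pivot_table(index=["patient_id", "date"], columns="activity_class",
                        values="steps", aggfunc="size", fill_value=0))
    out = pd.DataFrame({"Steps": steps}, dtype=float)
    for name, col in (("Light", "light"), ("Fair", "fair"), ("Vig", "vigorous")):
        out[name] = 15.0 * cls[col].astype(float) if col in cls else 0.0
    out["Light+Fair"] = out["Light"] + out["Fair"]
    out["Fair+Vig"] = out["Fair"] + out["Vig"]
    out["Active"] = out["Light"] + out["Fair"] + out["Vig"]
    n_cls = cls.drop(columns=[c for c in ("missing",) if c in cls]).sum(axis=1)
    out["n_classified_intervals"] = n_cls.reindex(out.index).fillna(0).astype(int)
    return out


def _sleep_day_table(sleep: pd.DataFrame) -> pd.DataFrame:
    date = sleep["minute"].dt.normalize()
    cls = (sleep.assign(date=date)
           .pivot_table(index=["patient_id", "date"], columns="sleep_class",
                        values="minute", aggfunc="size", fill_value=0))
    out = pd.DataFrame(index=cls.index)
    for name, col in (("Asleep", "asleep"), ("Awake", "awake"), ("Restless", "restless")):
        out[name] = cls[col].astype(float) if col in cls else 0.0
    unknown = cls["unknown"].astype(float) if "unknown" in cls else 0.0
    out["Asleep+Awake"] = out["Asleep"] + out["Awake"]
    out["Asleep+Restless"] = out["Asleep"] + out["Restless"]
    out["Awake+Restless"] = out["Awake"] + out["Restless"]
    out["Sleep"] = out["Asleep"] + out["Awake"] + out["Restless"] + unknown
    out["n_sleep_minutes"] = cls.sum(axis=1).astype(int)
    return out


def _hr_day_table(hr: pd.DataFrame) -> pd.DataFrame:
    frame = hr.assign(date=hr["minute"].dt.normalize(),
                      interval=hr["minute"].dt.floor("15min"))
    per_interval = (frame.groupby(["patient_id", "date", "interval"], observed=True)["bpm"]
                    .agg(["min", "mean", "median", "max", "std", "size"]))
    per_interval["std"] = per_interval["std"].where(per_interval["size"] > 1, 0.0)
    g = per_interval.groupby(["patient_id", "date"], observed=True)
    out = pd.DataFrame({
        "MinHR": g["min"].min(),
        "MeanHR": g["mean"].mean(),
        "MedianHR": g["median"].median(),
        "MaxHR": g["max"].max(),
        "SDHR": g["std"].mean(),
        "n_hr_minutes": g["size"].sum().astype(int),
    })
    return out


def day_aggregates(cohort: Cohort, variables: Iterable[str] | None = None) -> pd.DataFrame:
    """Daily behavior aggregates for every patient-date with data.

    Parameters
    ----------
    cohort
        zero-filtered cohort (see :func:`filter_zero_measurements`).
    variables
        restrict computation to the streams needed for these variables
        (activity is always computed — it also drives day validity).

    Returns a frame indexed by ``(patient_id, date)``.  Absent streams leave
    their variables NaN; availability counts (``n_classified_intervals``,
    ``n_sleep_minutes``, ``n_hr_minutes``) are always present.
    """
    wanted = set(BEHAVIOR_VARIABLES if variables is None else variables)
    unknown = wanted - set(BEHAVIOR_VARIABLES)
    if unknown:
        raise ValueError(f"unknown or excluded behavior variables: {sorted(unknown)}")

    parts = []
    if len(cohort.intervals):
        parts.append(_activity_day_table(cohort.intervals))
    if wanted & set(SLEEP_VARIABLES) and len(cohort.sleep):
        parts.append(_sleep_day_table(cohort.sleep))
    if wanted & set(HR_VARIABLES) and len(cohort.hr):
        parts.append(_hr_day_table(cohort.hr))
    if not parts:
        return pd.DataFrame(index=pd.MultiIndex.from_arrays([[], []], names=["patient_id", "date"]))
    out = parts[0]
    for p in parts[1:]:
        out = out.join(p, how="outer")
    if "n_classified_intervals" in out:
        out["n_classified_intervals"] = out["n_classified_intervals"].fillna(0).astype(int)
    return out.sort_index()


def aggregate_day(intervals: pd.DataFrame,
                  sleep: pd.DataFrame | None = None,
                  hr: pd.DataFrame | None = None) -> pd.Series:
    """Aggregate one patient-date directly (reference path for small inputs).

    Input frames must contain records of a single patient-date, already
    zero-filtered.  Returns a Series over the behavior variables; variables
    of absent streams are NaN.
    """
    out = pd.Series(np.nan, index=list(BEHAVIOR_VARIABLES), dtype=float)
    classified = intervals[intervals["activity_class"] != "missing"]
    out["Steps"] = float(intervals["steps"].sum())
    for name, cls in (("Light", "light"), ("Fair", "fair"), ("Vig", "vigorous")):
        out[name] = 15.0 * int((classified["activity_class"] == cls).sum())
    out["Light+Fair"] = out["Light"] + out["Fair"]
    out["Fair+Vig"] = out["Fair"] + out["Vig"]
    out["Active"] = out["Light"] + out["Fair"] + out["Vig"]
    if sleep is not None and len(sleep):
        for name, cls in (("Asleep", "asleep"), ("Awake", "awake"), ("Restless", "restless")):
            out[name] = float((sleep["sleep_class"] == cls).sum())
        out["Asleep+Awake"] = out["Asleep"] + out["Awake"]
        out["Asleep+Restless"] = out["Asleep"] + out["Restless"]
        out["Awake+Restless"] = out["Awake"] + out["Restless"]
        out["Sleep"] = float(len(sleep))
    if hr is not None and len(hr):
        stats = [interval_hr_stats(grp["bpm"].to_numpy())
                 for _, grp in hr.groupby(hr["minute"].dt.floor("15min"))]
        out["MinHR"] = min(s.min for s in stats)
        out["MeanHR"] = float(np.mean([s.mean for s in stats]))
        out["MedianHR"] = float(np.median([s.median for s in stats]))
        out["MaxHR"] = max(s.max for s in stats)
        out["SDHR"] = float(np.mean([s.sd for s in stats]))
    return out


def _aggregate_up(values: pd.DataFrame, unit: str, weekly_minhr: str) -> pd.Series:
    if not len(values):
        raise ValueError(f"cannot aggregate a {unit} with zero valid constituents")
    if weekly_minhr not in ("mean", "min"):
        raise ValueError("weekly_minhr must be 'mean' or 'min'")
    out = values.mean(axis=0, skipna=True)
    if weekly_minhr == "min" and "MinHR" in values:
        out["MinHR"] = values["MinHR"].min(skipna=True)
    return out


def aggregate_week(valid_day_values: pd.DataFrame, weekly_minhr: str = "mean") -> pd.Series:
    """Weekly aggregate: per-variable arithmetic mean over the valid days.

    The caller passes only the valid days of an already-valid week.  NaN
    daily values (stream absent that day) are skipped per variable.  With
    ``weekly_minhr="min"`` the weekly MinHR is the running minimum of the
    daily minima instead of their mean.
    """
    return _aggregate_up(valid_day_values, "week", weekly_minhr)


def aggregate_period(valid_week_values: pd.DataFrame, weekly_minhr: str = "mean") -> pd.Series:
    """Period aggregate: per-variable mean over the valid weeks (same rules)."""
    return _aggregate_up(valid_week_values, "period", weekly_minhr)
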