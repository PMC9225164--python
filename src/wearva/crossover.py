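"""Case/control period construction for the case-crossover design.

Every monitoring day ``d`` of every patient is an *index day* whose outcome
is "VA event on ``d``, yes/no".  Its exposure is the behavior aggregate of
the window of ``w`` weeks (1-8) ending the day *before* ``d`` — exposure
strictly precedes the outcome day.  The window is partitioned into ``w``
consecutive 7-day blocks counted backward from ``d - 1`` (weeks are
anchored to the window, not the calendar).  Under the active validity
scenario each block is a valid/invalid week, the window a valid/invalid
period; index days whose window is invalid, extends before the start of
monitoring, or carries no usable exposure value contribute nothing — they
are neither cases nor controls.

Each observation also carries the time covariates of its index day (the
date immediately succeeding the period): season by northern-hemisphere
meteorological convention, ISO day of week, and weekday/weekend status.
All of a patient's observations share one stratum, so the conditional
analysis cancels stable between-patient differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aggregate
from .cohort import Cohort
from .validity import MAX_PERIOD_WEEKS, ValidityScenario, day_validity_table

SEASONS = {12: "winter", 1: "winter", 2: "winter",
           3: "spring", 4: "spring", 5: "spring",
           6: "summer", 7: "summer", 8: "summer",
           9: "fall", 10: "fall", 11: "fall"}

OBSERVATION_COLUMNS = ("patient_id", "index_date", "duration_weeks", "outcome",
                       "exposure", "season", "day_of_week", "weekday_status")


def time_covariates(index_date) -> tuple[str, int, str]:
    """(season, ISO day-of-week 1-7, weekday/weekend) of one date."""
    ts = pd.Timestamp(index_date)
    dow = ts.isoweekday()
    return SEASONS[ts.month], dow, ("weekend" if dow >= 6 else "weekday")


def _window_series(valid: np.ndarray, value: np.ndarray, w: int,
                   scenario: ValidityScenario, minhr_min: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-index-position period validity and exposure.

    ``valid``/``value`` are aligned to consecutive dates starting at the
    first monitored day.  Position ``i`` is an index day; its window spans
    positions ``[i - 7w, i - 1]`` split into 7-day blocks counted backward.
    Returns boolean ``period_valid`` and float ``exposure`` (NaN where the
    period is invalid, out of range, or has no usable value).
    """
    n = valid.shape[0]
    period_valid = np.zeros(n, dtype=bool)
    exposure = np.full(n, np.nan)
    if n < 7 * w + 1:
        return period_valid, exposure

    has = valid & ~np.isnan(value)
    val0 = np.where(has, value, 0.0)
    cs_valid = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    cs_has = np.concatenate(([0], np.cumsum(has.astype(np.int64))))
    cs_val = np.concatenate(([0.0], np.cumsum(val0)))
    # k-indexed 7-day blocks covering positions [k, k+6], k = 0..n-7
    blk_valid_days = cs_valid[7:] - cs_valid[:-7]
    blk_has = cs_has[7:] - cs_has[:-7]
    with np.errstate(invalid="ignore"):
        blk_mean = np.where(blk_has > 0, (cs_val[7:] - cs_val[:-7]) / np.maximum(blk_has, 1), np.nan)
    if minhr_min:
        masked = pd.Series(np.where(has, value, np.nan))
        blk_mean = masked.rolling(7, min_periods=1).min().to_numpy()[6:]
    blk_week_valid = blk_valid_days >= scenario.week_min_valid_days

    idx = np.arange(n)
    n_valid_weeks = np.zeros(n, dtype=np.int64)
    agg_sum = np.zeros(n)
    agg_cnt = np.zeros(n, dtype=np.int64)
    agg_min = np.full(n, np.inf)
    feasible = idx - 7 * w >= 0
    for j in range(1, w + 1):
        k = idx - 7 * j  # block start positions; valid where feasible
        kc = np.clip(k, 0, blk_week_valid.shape[0] - 1)
        wv = blk_week_valid[kc] & feasible
        wm = blk_mean[kc]
        n_valid_weeks += wv
        usable = wv & ~np.isnan(wm)
        agg_sum += np.where(usable, np.nan_to_num(wm), 0.0)
        agg_cnt += usable
        agg_min = np.where(usable, np.minimum(agg_min, np.where(usable, wm, np.inf)), agg_min)

    # exact rational comparison: thresholds {.5, .75, 1.} and 7w-day windows
    # make count >= frac * w representable without rounding error
    period_valid = feasible & (n_valid_weeks >= scenario.period_min_valid_fraction * w)
    with np.errstate(invalid="ignore"):
        if minhr_min:
            exposure = np.where(period_valid & (agg_cnt > 0), agg_min, np.nan)
        else:
            exposure = np.where(period_valid & (agg_cnt > 0),
                                agg_sum / np.maximum(agg_cnt, 1), np.nan)
    return period_valid, exposure


def build_observations(cohort: Cohort, scenario: ValidityScenario,
                       duration_weeks: int, behavior: str, *,
                       day_table: pd.DataFrame | None = None,
                       weekly_minhr: str = "mean",
                       zero_filtered: bool = False) -> pd.DataFrame:
    """One case/control observation per monitoring day with a valid window.

    Parameters
    ----------
    cohort
        full cohort; zero filtering is applied here unless ``zero_filtered``.
    scenario
        active data-validity scenario.
    duration_weeks
        exact window length ``w`` in weeks, 1-8.
    behavior
        analysis variable whose period aggregate becomes the exposure.
    day_table
        optional precomputed :func:`wearva.aggregate.day_aggregates` output
        (must include ``behavior`` and be built from zero-filtered data).
    weekly_minhr
        ``"mean"`` averages daily MinHR upward; ``"min"`` takes the running
        minimum across valid days and weeks.

    Returns a frame with :data:`OBSERVATION_COLUMNS`; ``outcome`` is 1 iff
    the patient had at least one VA event on the index day (multiple events
    on a day collapse to one case).  ``attrs`` records scenario, behavior,
    and duration for downstream consistency checks.
    """
    if not 1 <= duration_weeks <= MAX_PERIOD_WEEKS:
        raise ValueError(f"duration_weeks must be 1..{MAX_PERIOD_WEEKS}, got {duration_weeks}")
    if behavior not in aggregate.BEHAVIOR_VARIABLES:
        raise ValueError(f"unknown or excluded behavior variable: {behavior!r}")

    work = cohort if zero_filtered else aggregate.filter_zero_measurements(cohort)
    if day_table is None:
        day_table = aggregate.day_aggregates(work, variables=[behavior])
    validity = day_validity_table(work.intervals, scenario.day_min_hours)
    validity = validity.set_index(["patient_id", "date"])["valid_day"]

    event_days = set(zip(work.events["patient_id"], work.events["date"].dt.normalize()))

    frames = []
    for _, row in work.calendar.iterrows():
        pid, first, last = row["patient_id"], row["first_day"], row["last_day"]
        dates = pd.date_range(first, last, freq="D")
        n = len(dates)
        mi = pd.MultiIndex.from_product([[pid], dates])
        valid = validity.reindex(mi, fill_value=False).to_numpy(dtype=bool)
        if behavior in day_table.columns:
            value = day_table[behavior].reindex(mi).to_numpy(dtype=float)
        else:
            value = np.full(n, np.nan)
        minhr_min = weekly_minhr == "min" and behavior == "MinHR"
        _, exposure = _window_series(valid, value, duration_weeks, scenario, minhr_min=minhr_min)
        keep = ~np.isnan(exposure)
        if not keep.any():
            continue
        kept_dates = dates[keep]
        frames.append(pd.DataFrame({
            "patient_id": pid,
            "index_date": kept_dates,
            "duration_weeks": duration_weeks,
            "outcome": [int((pid, d) in event_days) for d in kept_dates],
            "exposure": exposure[keep],
        }))

    if frames:
        obs = pd.concat(frames, ignore_index=True)
        months = obs["index_date"].dt.month
        obs["season"] = months.map(SEASONS)
        obs["day_of_week"] = obs["index_date"].dt.dayofweek + 1
        obs["weekday_status"] = np.where(obs["day_of_week"] >= 6, "weekend", "weekday")
    else:
        obs = pd.DataFrame(columns=list(OBSERVATION_COLUMNS))
    obs.attrs["scenario"] = scenario.label
    obs.attrs["behavior"] = behavior
    obs.attrs["durations"] = (duration_weeks,)
    return obs


def pool_combined(observation_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Multiset union of per-duration observation sets for a combined model.

    All member sets must come from the same scenario and behavior; one index
    day may contribute one observation per duration, all in the same patient
    stratum.
    """
    if not observation_sets:
        raise ValueError("pool_combined requires at least one observation set")
    keys = {(o.attrs.get("scenario"), o.attrs.get("behavior")) for o in observation_sets}
    if len(keys) > 1:
        raise ValueError(f"cannot pool observations from mixed scenarios/behaviors: {sorted(keys)}")
    pooled = pd.concat(observation_sets, ignore_index=True)
    pooled.attrs["scenario"], pooled.attrs["behavior"] = keys.pop()
    pooled.attrs["durations"] = tuple(sorted(
        d for o in observation_sets for d in o.attrs.get("durations", ())))
    return pooled
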