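"""Model-grid enumeration, suite execution, OR verdicts, and descriptives.

For one behavior variable the full sensitivity grid crosses

* 36 data-validity scenarios,
* 3 regression formulae (time-covariate sets),
* 2 model families — *separate* (periods of exactly ``w`` weeks) and
  *combined* (periods of all durations 1..``w`` pooled),
* 8 window durations ``w``,

for 36 x 3 x 2 x 8 = 1728 conditional-logit models per behavior (108
scenario-formula combinations, each fitted 8 + 8 times).  Running the grid
is bookkeeping, never judgment: each model records an estimate or a
structured failure, and the suite never aborts on one model.

A behavior's verdict aggregates its significant models (p < alpha,
converged): ``OR>1`` when every significant OR exceeds 1, ``OR<1`` when
every one is below 1, and *inconclusive* when none is significant or the
signs are mixed — comparisons to 1 at full precision, no multiplicity
adjustment.  ORs are reported per raw unit and can be rescaled to the
conventional reporting units (1000 steps, 15 minutes, 10 bpm) via
:func:`scale_or`.

The module also ships the published participant table of the study cohort
(27 ICD patients) as a fixture and reproduces its descriptive statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import aggregate, clogit, crossover
from .cohort import Cohort
from .validity import ValidityScenario, enumerate_scenarios

FAMILIES = ("separate", "combined")
DURATIONS = tuple(range(1, 9))

#: conventional per-unit scaling for reported ORs, by variable unit
REPORT_SCALE_UNITS = {"count": 1000, "minutes": 15, "bpm": 10}

#: |log-OR| beyond which a unit-scale estimate is flagged as quasi-separated
QUASI_SEPARATION_BETA = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the grid: scenario x formula x family x duration x behavior."""

    scenario: ValidityScenario
    formula: int
    family: str
    duration_weeks: int
    behavior: str

    def __post_init__(self):
        if self.formula not in clogit.FORMULAE:
            raise ValueError(f"formula must be in {sorted(clogit.FORMULAE)}")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be in {FAMILIES}")
        if self.duration_weeks not in DURATIONS:
            raise ValueError("duration_weeks must be 1..8")


@dataclass
class BehaviorVerdict:
    """Cross-model OR classification for one behavior."""

    behavior: str
    verdict: str                 # "OR>1" | "OR<1" | "inconclusive"
    supporting: pd.DataFrame     # the significant fits with their durations


def enumerate_models(behavior: str) -> list[ModelSpec]:
    """The 1728 model specs of one behavior, in deterministic order."""
    if behavior not in aggregate.BEHAVIOR_VARIABLES:
        raise ValueError(
            f"behavior {behavior!r} is unknown or excluded from analysis "
            f"(excluded: {aggregate.EXCLUDED_VARIABLES})")
    return [ModelSpec(sc, f, fam, w, behavior)
            for sc in enumerate_scenarios()
            for f in sorted(clogit.FORMULAE)
            for fam in FAMILIES
            for w in DURATIONS]


def run_suite(cohort: Cohort, behaviors, *, scenarios=None, formulae=(1, 2, 3),
              families=FAMILIES, durations=DURATIONS, alpha: float = 0.05,
              exact_limit: int = clogit.DEFAULT_EXACT_LIMIT, ties: str = "breslow",
              weekly_minhr: str = "mean") -> pd.DataFrame:
    """Fit (a subset of) the grid; one result row per attempted model.

    Returns a frame with the spec fields plus ``status`` ("ok" or a failure
    tag), the exposure estimate (``beta``, ``se``, ``or_``, ``p``), stratum
    counts, ``converged``, ``significant``, ``quasi_separated``, and an
    ``error`` message for structured failures.  Fitting failures
    (non-convergence, no informative strata, empty observation sets) are
    recorded, never raised.
    """
    behaviors = [behaviors] if isinstance(behaviors, str) else list(behaviors)
    for b in behaviors:
        if b not in aggregate.BEHAVIOR_VARIABLES:
            raise ValueError(f"behavior {b!r} is unknown or excluded from analysis")
    if not len(cohort.calendar):
        raise ValueError("empty cohort: no monitored patients")
    scenarios = list(enumerate_scenarios() if scenarios is None else scenarios)

    work = aggregate.filter_zero_measurements(cohort)
    day_table = aggregate.day_aggregates(work, variables=behaviors)

    rows = []
    for behavior in behaviors:
        for sc in scenarios:
            per_duration = {}
            for w in DURATIONS:
                if w in durations or ("combined" in families and w <= max(durations)):
                    per_duration[w] = crossover.build_observations(
                        work, sc, w, behavior, day_table=day_table,
                        weekly_minhr=weekly_minhr, zero_filtered=True)
            for family in families:
                for w in durations:
                    if family == "separate":
                        obs = per_duration[w]
                    else:
                        obs = crossover.pool_combined([per_duration[j] for j in range(1, w + 1)])
                    for f in formulae:
                        spec = ModelSpec(sc, f, family, w, behavior)
                        rows.append(_fit_one(spec, obs, alpha, exact_limit, ties))
    return pd.DataFrame(rows)


def _fit_one(spec: ModelSpec, obs: pd.DataFrame, alpha, exact_limit, ties) -> dict:
    row = {"behavior": spec.behavior, "scenario": spec.scenario.label,
           "formula": spec.formula, "family": spec.family,
           "duration_weeks": spec.duration_weeks,
           "n_obs": len(obs), "status": "ok", "error": "",
           "beta": np.nan, "se": np.nan, "or_": np.nan, "p": np.nan,
           "n_strata": 0, "n_case": 0, "n_control": 0,
           "converged": False, "significant": False, "quasi_separated": False,
           "method": ""}
    if not len(obs):
        row.update(status="no_observations", error="no valid periods under this scenario")
        return row
    try:
        fr = clogit.fit(obs, formula=spec.formula, exact_limit=exact_limit, ties=ties)
    except clogit.NoInformativeStrataError as exc:
        row.update(status="no_informative_strata", error=str(exc))
        return row
    row.update(beta=fr.beta, se=fr.se, or_=fr.or_, p=fr.p,
               n_strata=fr.n_strata, n_case=fr.n_case, n_control=fr.n_control,
               converged=fr.converged, method=fr.method, error=fr.message)
    if not fr.converged:
        row["status"] = "not_converged"
    row["significant"] = bool(fr.converged and np.isfinite(fr.p) and fr.p < alpha)
    row["quasi_separated"] = bool(abs(fr.beta) > QUASI_SEPARATION_BETA)
    return row


def classify_behavior(results: pd.DataFrame, alpha: float = 0.05) -> BehaviorVerdict:
    """Verdict over all models of one behavior.

    Significant = converged and p < alpha.  ``OR>1`` iff every significant
    OR exceeds 1, ``OR<1`` iff every one is below 1 (comparison at full
    precision), otherwise inconclusive — including the no-significant-model
    branch.  Order of the input rows never matters.
    """
    if not len(results):
        raise ValueError("classify_behavior requires at least one model result")
    behaviors = results["behavior"].unique() if "behavior" in results else ["?"]
    if len(behaviors) != 1:
        raise ValueError(f"results mix behaviors: {sorted(behaviors)}")
    conv = results["converged"].astype(bool) if "converged" in results else pd.Series(True, index=results.index)
    sig = results[conv & results["p"].notna() & (results["p"] < alpha)]
    if not len(sig):
        verdict = "inconclusive"
    elif (sig["or_"] > 1).all():
        verdict = "OR>1"
    elif (sig["or_"] < 1).all():
        verdict = "OR<1"
    else:
        verdict = "inconclusive"
    return BehaviorVerdict(behavior=str(behaviors[0]), verdict=verdict,
                           supporting=sig.reset_index(drop=True))


def scale_or(or_per_unit: float, k_units: float) -> float:
    """Rescale a per-unit OR to ``k`` units: OR^k (multiplicative in k)."""
    if not or_per_unit > 0:
        raise ValueError(f"odds ratio must be positive, got {or_per_unit}")
    return float(or_per_unit ** k_units)


def _weeks_label(weeks) -> str:
    """Compress sorted durations to the conventional range notation (e.g. '2-6, 8')."""
    weeks = sorted(set(int(w) for w in weeks))
    if not weeks:
        return "-"
    runs, lo, hi = [], weeks[0], weeks[0]
    for w in weeks[1:]:
        if w == hi + 1:
            hi = w
        else:
            runs.append((lo, hi))
            lo = hi = w
    runs.append((lo, hi))
    return ", ".join(f"{a}" if a == b else f"{a}-{b}" for a, b in runs)


def verdict_table(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Summary table: per behavior and family, the most significant OR, its
    p, the significant durations, and the overall verdict."""
    out = []
    for behavior, res in results.groupby("behavior"):
        verdict = classify_behavior(res, alpha=alpha)
        row = {"behavior": behavior}
        for family in FAMILIES:
            sig = verdict.supporting[verdict.supporting["family"] == family]
            if len(sig):
                best = sig.loc[sig["p"].idxmin()]
                row[f"{family}_or"] = best["or_"]
                row[f"{family}_p"] = best["p"]
                row[f"{family}_weeks"] = _weeks_label(sig["duration_weeks"])
            else:
                row[f"{family}_or"] = np.nan
                row[f"{family}_p"] = np.nan
                row[f"{family}_weeks"] = "-"
        row["verdict"] = verdict.verdict
        out.append(row)
    return pd.DataFrame(out)


def or_by_duration(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Forest-style plot data: significant ORs per (behavior, family, duration),
    rescaled to the conventional reporting units."""
    sig = results[results["converged"].astype(bool) & results["p"].notna()
                  & (results["p"] < alpha)].copy()
    if not len(sig):
        return pd.DataFrame(columns=["behavior", "family", "duration_weeks",
                                     "or_per_unit", "scale_units", "or_scaled", "p"])
    units = sig["behavior"].map(aggregate.UNITS).map(REPORT_SCALE_UNITS)
    sig["or_per_unit"] = sig["or_"]
    sig["scale_units"] = units
    sig["or_scaled"] = [scale_or(o, k) for o, k in zip(sig["or_"], units)]
    return sig[["behavior", "family", "duration_weeks", "or_per_unit",
                "scale_units", "or_scaled", "p"]].reset_index(drop=True)


# -- descriptive statistics on the packaged participant table --------------


def load_table4() -> pd.DataFrame:
    """The published participant table of the study cohort (27 rows)."""
    with resources.files("wearva.data").joinpath("table4_participants.csv").open() as fh:
        return pd.read_csv(fh)


def descriptive_summary(rows: pd.DataFrame) -> dict:
    """Participant-level summary statistics.

    Per-patient VA-event statistics are computed over patients with at
    least one event; monitoring-day and age statistics over all patients.
    Standard deviations use the sample (n-1) denominator.
    """
    if not len(rows):
        raise ValueError("descriptive_summary requires at least one participant")
    ev = rows["va_events"].astype(float)
    evp = ev[ev > 0]
    days = rows["fitbit_days"].astype(float)
    age = rows["age"].astype(float)
    return {
        "n_patients": int(len(rows)),
        "n_patients_with_events": int(len(evp)),
        "total_va_events": int(ev.sum()),
        "mean_events_per_event_patient": float(evp.mean()) if len(evp) else float("nan"),
        "sd_events_per_event_patient": float(evp.std(ddof=1)) if len(evp) > 1 else float("nan"),
        "total_fitbit_days": int(days.sum()),
        "mean_fitbit_days": float(days.mean()),
        "median_fitbit_days": float(days.median()),
        "sd_fitbit_days": float(days.std(ddof=1)) if len(days) > 1 else float("nan"),
        "median_age": float(age.median()),
        "mean_age": float(age.mean()),
        "sd_age": float(age.std(ddof=1)) if len(age) > 1 else float("nan"),
        "n_by_gender": rows["gender"].value_counts().to_dict(),
    }
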