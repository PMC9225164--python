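# Methods

This note records the modelling assumptions, defaults, and numerical
choices behind `wearva`, in the spirit of a statistical software appendix.

## Data model

Five record collections describe a cohort: 15-minute activity intervals
(steps + intensity class), 1-minute sleep classes, 1-minute heart rate,
daily VA events from the ICD, and a per-patient monitoring calendar.
Timestamps are ISO-8601, timezone-naive, and read as local clock time: the
8 a.m.–8 p.m. validity window and the midnight day boundary are clock-local
notions, and the devices themselves report local time.  A day is the
calendar date [00:00, 24:00); sleep spanning midnight is split across
dates, which is what bounds every stream at 1440 records per patient-day.
Events carry a date only — the outcome of interest is "VA on this day,
yes/no", and multiple episodes on one day collapse to a single case.
Structural validation rejects (never truncates) closed-set violations,
duplicate timestamps, off-grid interval starts, per-day record-count
overflows, and events outside the monitoring span.

## Validity scenarios

Data-availability is judged before anything is aggregated.  A day is valid
when at least *h* ∈ {1, 2, 4, 8} hours of classified 15-minute intervals
start in [08:00, 20:00) — counted as intervals (1 h = 4 intervals), because
the criterion is about the availability of data, and the interval is the
unit of availability; sedentary intervals count, since they are data even
though sedentary *durations* are excluded as analysis variables.  The
window is half-open on interval starts so the 20:00 interval is not double
counted.  A week (7 consecutive window-anchored days) is valid with ≥
{4, 5, 7} valid days; a period of *w* ∈ 1..8 weeks with a valid-week
fraction ≥ {0.50, 0.75, 1.00}, compared exactly on the rational count/*w*
(3/4 passes 0.75; 2/3 fails it).  The 4 × 3 × 3 grid gives 36 scenarios.
Relaxing any knob is monotone: it can only add valid units.

## Aggregation

Zero filtering precedes aggregation and acts per measurement: heart-rate
minutes of 0 bpm are discarded (they are non-wear artefacts), and interval
rows carrying no measurement at all (zero steps *and* no intensity class)
are dropped, while a genuine zero step count inside a classified interval
is retained.  Whether a zero count inside a sedentary interval should also
count as a "zero measurement" is not decidable from first principles; we
keep it, because the interval's class is evidence the device was worn.

Daily aggregates: steps are summed; each intensity duration is 15 × the
interval count of that class; sleep durations count minutes per class.
Combined variables are sums of their constituents (light+fair, fair+vig,
active = light+fair+vig; pairwise sleep combinations), holding exactly as
conservation identities.  'Unknown' sleep minutes enter only the cumulative
Sleep variable.  Sedentary-containing durations are excluded throughout:
the tracker cannot separate sedentary wear from sleep or non-wear.  Heart
rate is first reduced to per-15-minute statistics (min, mean, median, max,
sample SD with the n−1 denominator, 0 for a single minute), then composed
per day as min-of-mins, mean-of-means, median-of-medians, max-of-maxes,
and SDHR = mean of per-interval SDs — a within-interval variability
measure, consistent with its observed few-bpm magnitude, not a whole-day
SD.

Weekly and period aggregates are arithmetic means over valid constituents
only, per variable, skipping days on which a stream is absent.  All five
daily HR statistics are averaged upward; averaging the daily minimum
(rather than taking a running minimum) is the only reading under which the
week → period chain composes consistently, but since the alternative is
defensible, `weekly_minhr="min"` switches MinHR to a running minimum.  A
single-constituent aggregate equals its constituent, so the chain is
drift-free.

## Case-crossover construction

Weeks inside an exposure window are anchored to the window, not the
calendar: the *w*-week window ending at *d* − 1 is split into *w*
consecutive 7-day blocks counted backward.  Calendar-aligned weeks would
misalign exposure with the outcome day.  Exposure strictly precedes the
index day, and the index day's own covariates (season by northern-
hemisphere meteorological convention, ISO day of week, weekday/weekend)
adjust for time.  Index days whose window is invalid, leaves the monitoring
calendar, or yields no usable exposure value (e.g. no valid day carries the
sleep stream) contribute nothing — they are neither cases nor controls.
Consecutive index days have overlapping windows; the resulting
within-stratum dependence is inherent to the one-period-per-monitoring-day
design and is acknowledged rather than corrected.  Event days are not
excluded from later windows (no washout).  Combined models pool the
observation sets of durations 1..*w* as a multiset union within the same
patient strata.

## Conditional logistic regression

The stratum contribution conditions on the number of cases *m* among the
*n* rows of a patient, summing the denominator over all size-*m* subsets.
Strata that are all-case or all-control are non-informative and dropped;
covariate columns (never the exposure) constant within every informative
stratum are unidentifiable under conditioning and are removed before
fitting.  Dummy coding uses fixed reference levels (spring, weekday, day 1)
for reproducibility, and exposures stay on their raw unit scale so the
reported OR is per step, minute, or bpm.

Per stratum the likelihood is exact when C(*n*, *m*) ≤ 100,000 (vectorised
subset enumeration) and otherwise uses the Breslow approximation for the
*m* tied "failures" over the stratum risk set, switchable to Efron.  Both
approximations coincide with the exact likelihood at *m* = 1 and differ
from it by an almost-constant offset (−*m* log *n* vs −log C(*n*, *m*))
that cancels in estimation.  Optimisation is Newton–Raphson from β = 0 with
step-halving on likelihood decrease, converging when the relative
log-likelihood change is < 1e-10 (max 50 iterations); standard errors come
from the inverse observed information and significance from the two-sided
Wald normal test.  Non-convergence, a singular information matrix, and a
likelihood reaching its supremum of 1 (perfect within-stratum separation)
are reported as structured diagnostics, never as silent estimates;
unit-scale |β̂| > 10 is additionally flagged as quasi-separation in suite
output.

## Model suite and verdicts

Per behavior, the grid crosses 36 scenarios × 3 formulae × 2 families × 8
durations = 1728 models (108 scenario-formula combinations); the suite
records an estimate or a structured failure per cell and never aborts.  A
verdict aggregates all of a behavior's models across both families:
**OR > 1** if every significant (converged, p < α = 0.05) OR exceeds 1,
**OR < 1** if every one is below 1, otherwise **inconclusive** — with
comparisons to 1 at full floating-point precision and no multiplicity
adjustment.  Failed fits are excluded from verdicts but logged.  Reported
ORs can be rescaled as OR^k to the conventional units (1000 steps,
15 minutes, 10 bpm).

## Synthetic cohort generator

The generator is first-class, tested code, not a fixture.  Defaults were
calibrated once to the observed magnitudes of the study population this
pipeline targets — about 7668 steps/day, 353 light / 43 fair / 61 vigorous
minutes/day, daily-minimum HR near 50 bpm, maximum near 125 bpm,
within-interval HR SD near 4 bpm, and an event rate near 0.022 per
monitored day (intercepts α_i ~ N(−3.8, 0.8²)) — and are not tuned
afterwards.  Concretely: per-interval wear probability 0.95 by day and
0.60 by night; intensity mixture (sedentary 0.585, light 0.32, fair 0.04,
vigorous 0.055) with Poisson step rates (8, 140, 420, 760 per interval);
a 23:00–07:00 sleep window recorded at only 0.55 per minute — deliberately
sparse, mirroring how unreliably consumer trackers capture sleep — with
class mixture (asleep 0.75, restless 0.12, awake 0.08, unknown 0.05);
heart rate as a sinusoidal diurnal mean (base 68, amplitude 10 bpm,
acrophase 16:00) plus intensity-dependent elevation (up to +55 bpm) and
N(0, 4.2²) noise.  Event types are drawn with the observed composition
(VT 56/262, VT1 172/262, VF-VT 34/262; VT2 carries zero mass).  Start
dates are staggered uniformly over a year so seasons vary across patients.

Daily events are Bernoulli with logit α_i + Σ_k effect_k · (X_k(d) −
mean X_k), where X_k(d) is the behavior aggregated over the configured lag
window by the *same* day → week → period chain the analysis uses (under
the most permissive scenario) — this circularity is intentional: it makes
parameter recovery a well-posed test, and the per-patient α_i make it a
direct test that stratification absorbs between-patient differences.
Exposures are centred at their cohort mean so the baseline logit keeps its
marginal meaning (zero effects ⇒ event rate = logistic(α)); centring
shifts the intercept only and leaves the recoverable log-OR unchanged.
Days with an unavailable lag exposure contribute the baseline hazard.

What the generator does *not* emulate: physiological HR waveforms or
exercise sessions beyond interval-level elevation, autocorrelated
behavior (days are exchangeable given the patient), behavior drift before
events, device feedback effects, or clinical covariates.  Passing
parameter-recovery tests therefore demonstrates the pipeline's correctness
under its own assumptions, not the clinical validity of any association in
real data.

## Problem sizes and seeds

Simulation-based checks use 20 patients × 180 days.  CI-coverage of an
injected light-activity log-OR of 0.01/min uses 20 replicates (seeds
101–120) in the test suite; null type-I calibration uses 50 replicates
(seeds 201–250) against the central 95 % binomial band at α = 0.05.  For
these runs the sleep and HR streams are disabled in the configuration —
they play no role in a light-activity fit — and structural re-validation
of generator output is skipped; both are problem-size choices, exercised
elsewhere.  The acceptance script scales to 10 recovery and 25 null
replicates, with all seeds derived from its `--seed` argument.

## Known limitations

* The Wald SE ignores the overlap of consecutive exposure windows; the
  conditional likelihood is still correctly specified for the generator's
  day-wise independent outcomes, but real carry-over would violate it.
* Extreme ORs under quasi-separation are reported as computed, with a
  flag; no penalised (Firth-type) fallback is provided.
* Only the all-monitoring-days referent scheme is implemented — no
  time-stratified bidirectional sampling.
* The conditional likelihood-ratio and score tests are not implemented;
  inference is Wald-only.
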