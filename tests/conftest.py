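import pandas as pd
import pytest

from wearva import SimulationConfig, day_aggregates, filter_zero_measurements, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 5-patient x 10-week cohort used across modules."""
    cfg = SimulationConfig(n_patients=5, days_per_patient=70, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_day_table(small_cohort):
    return day_aggregates(filter_zero_measurements(small_cohort))


def make_intervals(pid, date, hours, klass="light", steps=100):
    """Interval rows at the given clock hours (one 15-min interval each)."""
    base = pd.Timestamp(date)
    return pd.DataFrame({
        "patient_id": pid,
        "start": [base + pd.Timedelta(hours=h) for h in hours],
        "steps": steps,
        "activity_class": klass,
    })
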