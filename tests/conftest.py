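import numpy as np
import pandas as pd
import pytest

from weartime import CohortConfig, build_person_days, generate_cohort


def random_step_table(rng, n_persons=4, n_days=8, p_day=0.8, p_hour=0.4, max_steps=800):
    """A small random hourly step table plus its participant table."""
    rows = []
    persons = [f"p{i}" for i in range(n_persons)]
    base = pd.Timestamp("2020-03-01")
    for pid in persons:
        for d in range(n_days):
            if rng.random() > p_day:
                continue
            date = base + pd.Timedelta(days=d)
            hours = rng.choice(24, size=rng.integers(1, 12), replace=False)
            for h in hours:
                if rng.random() < p_hour:
                    steps = int(rng.integers(0, max_steps))
                else:
                    steps = 0
                rows.append((pid, date, int(h), steps))
    steps = pd.DataFrame(rows, columns=["person_id", "date", "hour", "steps"])
    participants = pd.DataFrame(
        {
            "person_id": persons,
            "group": ["case" if i % 2 == 0 else "control" for i in range(n_persons)],
            "age_band": ["<40" if i % 3 == 0 else "40-60" for i in range(n_persons)],
            "sex": ["female" if i % 2 == 0 else "male" for i in range(n_persons)],
        }
    )
    return steps, participants


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest confounded synthetic cohort shared by read-only tests."""
    config = CohortConfig(n_cases=25, n_controls=25, n_days=40, seed=42)
    participants, steps = generate_cohort(config)
    days = build_person_days(steps, participants)
    return config, participants, steps, days
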