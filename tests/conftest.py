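import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import taplearn as tl

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def main_cohort():
    """One seeded main-scenario cohort shared across tests."""
    return tl.scenario_cohort("main", seed=11)


@pytest.fixture(scope="session")
def toy_2x2():
    """Hand-computable 2x2 design with two observations per cell."""
    factors = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(8)],
            "A": ["a0", "a0", "a0", "a0", "a1", "a1", "a1", "a1"],
            "B": ["b0", "b0", "b1", "b1", "b0", "b0", "b1", "b1"],
        }
    )
    y = np.array([1.0, 3.0, 2.0, 4.0, 5.0, 7.0, 6.0, 8.0])
    return y, factors


@pytest.fixture(scope="session")
def one_group_lownoise():
    """Eight subjects from one population, near-noiseless day-1 data."""
    rng = np.random.default_rng(42)
    hypers = tl.GroupHyperParams(
        {"g": tl.GroupHyper(mu_I=8.0, mu_C=8.0, mu_R=0.6,
                            sigma_I=1.5, sigma_C=1.5, sigma_R=0.05)}
    )
    rows, truth = [], {}
    factors = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(8)],
            "piano": ["non-player"] * 8,
            "age_group": ["younger"] * 8,
            "intelligence": ["control"] * 8,
            "gender": ["female"] * 8,
            "age_years": 25.0,
            "piano_hours": 0.0,
            "delay": "24h",
        }
    )
    for sid in factors["subject_id"]:
        params = tl.synthgen.draw_subject_params(hypers, "g", rng)
        y = tl.simulate_day1(params, 12, 0.01, rng)
        truth[sid] = params
        rows += [(sid, "day1", t, v) for t, v in enumerate(y, start=1)]
    trials = pd.DataFrame(
        rows, columns=["subject_id", "session", "trial", "correct_sequences"]
    )
    return trials, factors, truth
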