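import numpy as np
import pandas as pd
import pytest

from organclock import CohortConfig, run_pipeline, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_participants=4000,
        seed=7,
        disease_prevalence_target=0.05,
        gp_coverage=0.6,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def pipeline_result(small_config):
    return run_pipeline(small_config)


def make_participants(
    n: int,
    seed: int = 0,
    age=None,
    sex=None,
) -> pd.DataFrame:
    """Minimal hand-rolled participant table for direct model tests."""
    # offset stream so tests drawing from default_rng(seed) stay independent
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    idx = pd.Index([f"P{i:06d}" for i in range(n)], name="participant_id")
    table = pd.DataFrame(
        {
            "age": rng.uniform(37, 73, n) if age is None else np.asarray(age, dtype=float),
            "sex": rng.choice(["male", "female"], n) if sex is None else sex,
            "bmi": rng.normal(27, 4, n),
            "packyears": rng.exponential(6, n),
            "alcohol": rng.choice(["0", "1", "missing"], n),
        },
        index=idx,
    )
    for k in range(1, 11):
        table[f"pc{k}"] = rng.normal(size=n)
    return table
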