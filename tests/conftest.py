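import numpy as np
import pandas as pd
import pytest

import loggerhead as lh


@pytest.fixture(scope="session")
def m1_table():
    return lh.project(lh.ModelConfig(variant="M1"))


@pytest.fixture(scope="session")
def m1_summary(m1_table):
    return lh.age_group_summary(m1_table)


@pytest.fixture(scope="session")
def synth_schedule():
    """Recruitment schedule driven by the default seeded synthetic index."""
    monthly = lh.synth_amo(lh.SynthAmoConfig(seed=1))
    annual = lh.seasonal_annual_mean(monthly)
    z = lh.normalize(annual, (1856, 2020))
    sums = lh.cohort_window_sums(z)
    return lh.assign_recruitment(sums, default_nr=10)


@pytest.fixture(scope="session")
def variant_summaries(synth_schedule):
    """Age-group summaries for M2-M5 under the synthetic driver."""
    out = {}
    for variant in ("M2", "M3", "M4", "M5"):
        table = lh.project(lh.ModelConfig(variant=variant,
                                          schedule=synth_schedule))
        out[variant] = lh.age_group_summary(table)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
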