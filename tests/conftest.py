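import numpy as np
import pytest

import cd4joint as cj

REDUCED_TERMS = ["age", "female", "adherence_poor", "adherence_fair"]
LONG_TERMS = ["intercept", "age", "female", "adherence_poor", "adherence_fair", "time"]
SURV_TERMS = ["intercept", "age", "female", "adherence_poor", "adherence_fair"]


@pytest.fixture(scope="session")
def preset():
    """Reference-calibration truth restricted to a desk-scale covariate set."""
    return cj.table_preset(REDUCED_TERMS)


@pytest.fixture(scope="session")
def small_cohort(preset):
    """A 150-patient cohort with dropout and MCAR missingness."""
    return cj.simulate_cohort(150, params=preset, seed=42)


@pytest.fixture(scope="session")
def medium_cohort(preset):
    """A 300-patient cohort used by the slower fitting tests."""
    return cj.simulate_cohort(300, params=preset, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fast_settings():
    return cj.McmcSettings(
        chains=1, iterations=800, burn=400, thin=1, seed=11, adapt_interval=25
    )
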