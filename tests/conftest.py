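import numpy as np
import pytest

from seqprog.synthetic_cohort import (CohortConfig, PhantomConfig,
                                      generate_cohort, generate_phantom)


@pytest.fixture(scope="session")
def cohort_small():
    """250-patient cohort under default study conditions."""
    df, truth = generate_cohort(CohortConfig(n_patients=250, seed=0))
    return df, truth


@pytest.fixture(scope="session")
def cohort_large():
    """2000-patient cohort for estimation-quality checks."""
    df, truth = generate_cohort(CohortConfig(n_patients=2000, seed=11))
    return df, truth


@pytest.fixture(scope="session")
def phantom():
    """One default phantom triple (ct, pet, mask)."""
    return generate_phantom(PhantomConfig(seed=3, aggressiveness=0.5))


def random_survival_data(rng, n, censor_frac=0.3):
    """Continuous, tie-free censored outcomes for oracle comparisons."""
    times = rng.exponential(10.0, n) + rng.uniform(0, 1e-3, n)
    events = rng.uniform(size=n) > censor_frac
    risks = rng.normal(size=n)
    return risks, events, times
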