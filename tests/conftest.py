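import numpy as np
import pytest

from thiastat.simulate import CohortConfig, DeficiencyPlan, generate


@pytest.fixture(scope="session")
def healthy_cohort():
    """60-animal cohort with no planted deficiency (seed 11)."""
    cfg = CohortConfig(n_animals=60, seed=11, deficiency_plan=DeficiencyPlan(0, 0, 0))
    return generate(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default 60-animal cohort with the 8+7+1 planted deficiency plan."""
    return generate(CohortConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
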