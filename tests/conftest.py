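import numpy as np
import pytest

from paceshape import SimConfig, build_default_grid, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort on the default 28-diet design, shared by tests."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_summary(default_cohort):
    from paceshape import summarise_cohort

    return summarise_cohort(default_cohort, grid=build_default_grid())


@pytest.fixture()
def rng():
    return np.random.default_rng(20231109)
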