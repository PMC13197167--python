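import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_config():
    """A reduced population for fast pipeline tests (4 trees per group in
    experiment 1; 18 + 8 x 9 in experiment 2, so control groups survive QC)."""
    from beechpheno.simulate import SimConfig

    return SimConfig(seed=7, n_trees_exp1=40, n_trees_exp2=90)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size simulated dataset at the study conditions (seed 3)."""
    from beechpheno.simulate import SimConfig, simulate_dataset

    return simulate_dataset(SimConfig(seed=3))
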