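import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from jshape.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-structure cohort for fast pipeline tests."""
    return simulate_cohort(SimulationConfig(n_participants=1500, n_waves=4, seed=42))


@pytest.fixture(scope="session")
def full_cohort():
    """Full-size default cohort (16,563 participants, 6 waves)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def no_confounding_config():
    """Exposure and outcome share no causes; censoring uninformative."""
    return SimulationConfig(
        n_participants=4000,
        n_waves=4,
        seed=11,
        confounder_to_exposure=(0.0, 0.0, 0.0, 0.0),
        female_to_exposure=(0.0, 0.0, 0.0, 0.0),
        confounder_to_censoring=0.0,
        category_to_censoring=(0.0, 0.0, 0.0, 0.0),
    )
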