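import numpy as np
import pytest

from pkdvol import phantom, pipeline


@pytest.fixture(scope="session")
def desk_spec():
    return pipeline.desk_phantom_spec(seed=7)


@pytest.fixture(scope="session")
def desk_case(desk_spec):
    """One deterministic desk-scale phantom with cysts, liver and noise."""
    return phantom.generate_case(desk_spec, case_seed=3, target_tkv_ml=110.0)


@pytest.fixture(scope="session")
def small_cohort(desk_spec):
    return phantom.generate_cohort(desk_spec, 3, (50.0, 150.0))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
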