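import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from waiome import default_generator_config, make_canonical_grids, sample_cohort
from waiome.preprocess import preprocess_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grids():
    return make_canonical_grids()


@pytest.fixture(scope="session")
def default_config():
    return default_generator_config()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced default-calibration cohort on canonical grids."""
    cfg = default_generator_config(n_normal=60, n_ome=36)
    cohort, rejections = preprocess_cohort(sample_cohort(cfg, seed=11))
    assert not rejections
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(2021)
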