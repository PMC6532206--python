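import warnings

import pytest
from hypothesis import HealthCheck, settings

from lungcea import load_base_case, run_psa

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

TEST_SEED = 1234


@pytest.fixture(scope="session")
def base():
    return load_base_case()


@pytest.fixture(scope="session")
def base_psa(base):
    """The base-case 1000-draw PSA shared by the acceptance checks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_psa(base, n_sims=1000, seed=TEST_SEED)
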