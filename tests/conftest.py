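import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from delamod import StefanParams, fd_solve

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: reference parameter set used across the Stefan-model tests
REF_PARAMS = StefanParams(D=1e-6, C0=1.0, S=10.0)


@pytest.fixture(scope="session")
def fd_reference():
    """One finite-difference reference run shared by several tests."""
    return fd_solve(REF_PARAMS, t_end=2e5, nx=160)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
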