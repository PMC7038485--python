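import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hrmood

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sessions():
    """One full synthetic study at the default scenario (25 x 3 sessions)."""
    return hrmood.simulate_study(hrmood.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_sessions):
    """Feature matrix of the default study (75 x 53)."""
    return hrmood.matrix_from_sessions(default_sessions)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_integer_series(rng, n, low=55, high=110):
    """A random-walk-ish integer BPM series with plateaus, as wearables emit."""
    steps = rng.choice([-2, -1, 0, 0, 1, 2], size=n - 1)
    values = np.clip(np.cumsum(np.concatenate([[0], steps])) + rng.integers(low, high), 35, 210)
    return values.astype(float)
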