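import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from sessa import SyntheticSpec, make_feature_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted():
    """Small planted dataset: 5 informative, 5 redundant, 40 noise columns."""
    spec = SyntheticSpec(
        n_samples=120, n_informative=5, n_redundant=5, n_noise=40,
        effect_size=2.0, seed=11,
    )
    X, y, truth = make_feature_dataset(spec)
    return X, y, truth


@pytest.fixture(scope="session")
def planted_arrays(planted):
    X, y, _ = planted
    return X.values, y.values


@pytest.fixture
def rng():
    return np.random.default_rng(123)
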