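import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """40 samples x 6 null markers with 2 covariates and a binary outcome."""
    from robustewas import Dataset

    n, m, c = 40, 6, 2
    outcome = np.repeat([0.0, 1.0], n // 2)
    covariates = rng.standard_normal((n, c))
    markers = rng.standard_normal((m, n))
    return Dataset(outcome=outcome, markers=markers, covariates=covariates)
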