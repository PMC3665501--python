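import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def balanced_phenotype():
    """Four controls followed by four cases."""
    from epiroc import PhenotypeVector

    return PhenotypeVector(np.array([0, 0, 0, 0, 1, 1, 1, 1]))
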