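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
def blobs_2c():
    """Two well-separated classes (centers 6 sigma apart), n=200."""
    from roundlvq.synthetic import BlobSpec, make_blobs

    return make_blobs(BlobSpec(classes=2, n_per_class=100, spread=1.0, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
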