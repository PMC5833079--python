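import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20180302)


@pytest.fixture
def random_pvector_batch(rng):
    """Batches of random p-value vectors with mixed signal/null composition."""

    def make(n_batches: int, max_m: int = 64, min_m: int = 1):
        out = []
        for _ in range(n_batches):
            m = int(rng.integers(min_m, max_m + 1))
            # mixture of uniform nulls and right-skewed "signal" p-values
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
            out.append(p)
        return out

    return make
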