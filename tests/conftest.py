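import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20230503)


@pytest.fixture
def small_matrix(rng):
    """A 12x4 feature matrix with one linear pair, validated and z-scored."""
    from sidcor import io_validate as iov

    x = rng.normal(size=12)
    vals = np.column_stack([
        x,
        2.0 * x + rng.normal(0, 0.2, size=12),
        rng.normal(size=12),
        rng.normal(size=12),
    ])
    raw = iov.RawTable(
        tuple(f"S{i}" for i in range(12)), ("A", "B", "C", "D"), vals)
    return iov.zscore(iov.validate(raw))
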