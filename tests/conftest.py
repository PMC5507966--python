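import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pair(seed: int, n: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """A reproducible continuous (x, y) pair with no ties."""
    r = np.random.default_rng(seed)
    return r.standard_normal(n), r.standard_normal(n)
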