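import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """A tiny deterministic count matrix with a mito gene."""
    from orgscope.scqc import CountMatrix

    X = np.array(
        [
            [5, 0, 100, 0],
            [3, 0, 200, 1],
            [0, 900, 0, 0],
            [2, 0, 50, 0],  # MT- gene
        ]
    )
    return CountMatrix(X, ["GA", "GB", "GC", "MT-1"], ["c0", "c1", "c2", "c3"])
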