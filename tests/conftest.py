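import numpy as np
import pytest
from hypothesis import settings

from sparcc import CountTable, FractionTable

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_counts():
    return CountTable(
        np.array([[3, 1, 0, 7], [0, 4, 2, 9], [5, 5, 5, 5]]),
        sample_ids=["s1", "s2", "s3"],
        component_ids=["a", "b", "c", "d"],
    )


@pytest.fixture
def random_fractions(rng):
    """Positive fraction table with 6 roughly independent components."""
    a = np.exp(rng.standard_normal((40, 6)))
    return FractionTable(a / a.sum(axis=1, keepdims=True))
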