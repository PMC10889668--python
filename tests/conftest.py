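import numpy as np
import pytest

from hydrogb.data_model import SampleTable, discretize_target
from hydrogb.synthetic import SyntheticSpec, generate


@pytest.fixture
def tiny_table():
    """5 samples, 2 attributes, easily checked by hand."""
    return SampleTable(
        values=np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]]),
        target=np.array([10.0, 20.0, 30.0, 40.0, 50.0]),
        attribute_names=["a", "b"],
    )


@pytest.fixture
def separable_table():
    """Two well-separated clusters of 5 samples each; labels follow the clusters."""
    rng = np.random.default_rng(42)
    low = rng.normal(0.0, 0.05, size=(5, 2))
    high = rng.normal(10.0, 0.05, size=(5, 2))
    values = np.vstack([low, high])
    target = np.array([1.0] * 5 + [100.0] * 5)
    return SampleTable(values=values, target=target)


@pytest.fixture
def separable_labels(separable_table):
    return discretize_target(separable_table, q=2)


@pytest.fixture
def planted_table():
    """Labels driven by attribute 0 alone; attributes 1-2 are i.i.d. noise."""
    rng = np.random.default_rng(7)
    n = 60
    signal = np.sort(rng.normal(0.0, 1.0, size=n))
    values = np.column_stack([signal, rng.normal(size=n), rng.normal(size=n)])
    return SampleTable(values=values, target=1000.0 * np.exp(signal))


@pytest.fixture
def paper_like_table():
    return generate(SyntheticSpec(seed=3))
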