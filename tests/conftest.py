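import numpy as np
import pytest

from countperm import HWE_EXAMPLE_TABLE, CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def example_table() -> CountTable:
    """Reference n=10,000 table (MAF 0.45, phenotype zero-prob 0.66)."""
    return HWE_EXAMPLE_TABLE


@pytest.fixture
def tiny_table() -> CountTable:
    """n=6 table small enough for exhaustive label-placement enumeration."""
    layer0 = np.zeros((3, 3), dtype=int)
    layer1 = np.zeros((3, 3), dtype=int)
    layer0[0, 0], layer1[0, 0] = 2, 1
    layer0[1, 1], layer1[1, 1] = 2, 1
    return CountTable.from_layers(layer0, layer1)
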