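import numpy as np
import pytest

from dosetrx.simulate import make_design
from dosetrx.types import CountMatrix


@pytest.fixture(scope="session")
def design24():
    """The study layout: 4 groups x 6 replicates."""
    return make_design(6)


@pytest.fixture()
def tiny_counts():
    """2 genes x 2 samples with lengths, for formula-level checks."""
    return CountMatrix(
        genes=["gA", "gB"], samples=["s1", "s2"],
        counts=np.array([[10, 10], [20, 20]]),
        lengths=np.array([1000.0, 2000.0]),
    )
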