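import numpy as np
import pytest

from fwmap.data import SampleStack
from fwmap.simulate import SimulationParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240416)


@pytest.fixture
def tiny_stack(rng):
    """12 random samples of a 7x6x5 volume with a ragged mask."""
    data = rng.normal(size=(12, 7, 6, 5))
    labels = np.array([1] * 6 + [-1] * 6)
    mask = rng.random((7, 6, 5)) > 0.2
    return SampleStack(data=data, labels=labels, mask=mask)


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale synthetic data set (30 x 66x22x22, offset 0.5)."""
    return generate_dataset(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """Reduced synthetic data set: one thin pair in a 24x12x12 volume."""
    params = SimulationParams(shape=(24, 12, 12), thicknesses=(1,), gaps=(2,),
                              seed=3)
    return generate_dataset(params)
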