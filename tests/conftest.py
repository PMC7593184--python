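import numpy as np
import pytest

from mitosel.simulate import SimulationParams

UNIFORM = np.full(3, 1.0 / 3.0)


@pytest.fixture
def det_params() -> SimulationParams:
    """Deterministic (infinite-population, noise-free) simulation parameters."""

    return SimulationParams(deterministic_mode=True, seed=0)


@pytest.fixture
def params() -> SimulationParams:
    return SimulationParams(seed=0)
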