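import numpy as np
import pytest

from ihdyn import ModelParameters
from ihdyn import _kernels


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba kernels once up front so individual test timings
    reflect the integration work, not JIT latency."""
    _kernels.warm_up()


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def default_params():
    return ModelParameters()


def random_states(rng, n):
    """Physiologically plausible random states for derivative checks."""
    V = rng.uniform(-90.0, 20.0, n)
    g = rng.uniform(0.02, 0.98, (n, 3))
    return np.column_stack([V, g])
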