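import numpy as np
import pytest

from drivedisp import kernels
from drivedisp.population import Population, SimulationState


@pytest.fixture(autouse=True)
def _seed_kernels():
    """Deterministic kernel RNG stream for every test."""
    kernels.seed_rng(123456789)


def _full(n, value, dtype):
    arr = np.asarray(value)
    if arr.ndim == 0:
        return np.full(n, value, dtype=dtype)
    return arr.astype(dtype)


@pytest.fixture
def make_population():
    """Factory for hand-built populations; scalar arguments broadcast."""

    def factory(n, sex=0, age=1, patch=0, allele_a=0, allele_b=0,
                d0a=0.5, d1a=0.0, d0b=0.5, d1b=0.0, dom=0) -> Population:
        return Population(
            sex=_full(n, sex, np.uint8),
            age=_full(n, age, np.int64),
            patch=_full(n, patch, np.int64),
            allele_a=_full(n, allele_a, np.uint8),
            allele_b=_full(n, allele_b, np.uint8),
            d0a=_full(n, d0a, np.float64),
            d1a=_full(n, d1a, np.float64),
            d0b=_full(n, d0b, np.float64),
            d1b=_full(n, d1b, np.float64),
            dom=_full(n, dom, np.uint8),
        )

    return factory


@pytest.fixture
def make_state(make_population):
    """Factory for a full simulation state with explicit patch capacities."""

    def factory(pop: Population, capacities, turn: int = 0) -> SimulationState:
        return SimulationState(
            turn=turn, population=pop,
            capacities=np.asarray(capacities, dtype=np.int64))

    return factory
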