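import numpy as np
import pytest

from lfpdyn.studies import lorenz_series
from lfpdyn.synth import MLParams, simulate_ml
from lfpdyn.timeseries import TimeSeries


@pytest.fixture(scope="session")
def lorenz10k() -> TimeSeries:
    """Standard Lorenz-63 x-coordinate, 10^4 points at dt=0.01."""
    return TimeSeries(lorenz_series(10_000), dt=0.01)


@pytest.fixture(scope="session")
def ml_trace() -> TimeSeries:
    """Noise-free Morris-Lecar membrane potential, 2 s at 0.5 ms sampling."""
    return simulate_ml(MLParams(), duration=2.0, dt=5e-4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def sine_series(n: int = 4000, period: int = 200, dt: float = 1e-3) -> TimeSeries:
    return TimeSeries(np.sin(2 * np.pi * np.arange(n) / period), dt=dt)
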