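import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from macrodiv import barcode_io, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_world():
    """One small synthetic world shared by read-only integration tests."""
    config = simulate.SimulationConfig(
        n_species=60, n_cells_x=12, n_cells_y=8, seed=7,
        mean_cells_per_species=6.0,
    )
    return simulate.simulate_dataset(config)


@pytest.fixture
def to_records():
    return barcode_io.records_from_frame
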