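import numpy as np
import pytest

from peritrack import synthcell


@pytest.fixture(scope="session")
def small_config():
    """A fast rendering configuration used by several image-level tests."""
    return synthcell.SimulationConfig(
        n_cells=12,
        duration_s=120.0,
        frame_interval_s=30.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
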