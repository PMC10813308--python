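import numpy as np
import pytest
from hypothesis import settings

from specklequant import speckle_sim as sim
from specklequant.config import load_config

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_grid():
    return sim.SimulationGrid(width=64, height=64)


@pytest.fixture(scope="session")
def small_basis(small_grid):
    return sim.build_mode_basis(8, small_grid, seed=7)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale pipeline config small enough for unit tests: 64x64
    render, 5 modes is enough speckle for ZNCC statistics."""
    return load_config(
        overrides={
            "seed": 11,
            "grid": {"width": 64, "height": 64},
            "modes": {"M": 12},
            "dataset": {"per_class": 8},
            "cnn": {"downsample": 2, "epochs": 4, "conv_blocks": [[4, 3, 2], [8, 3, 2]], "dense_width": 16},
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
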