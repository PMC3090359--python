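import numpy as np
import pytest

from sproutsim.config import SimulationConfig
from sproutsim.grid import GridState


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """Small, fully stochastic configuration for fast end-to-end runs."""
    return SimulationConfig(
        rows=12,
        cols=12,
        ini_ec=8,
        n_vegf=20,
        n_svegfr1=6,
        n_ado=4,
        num_cycles=6,
        p_execute=0.5,
        ruleset="R2",
        seed=11,
    )


def make_grid(rows: int = 5, cols: int = 5, ec=(), vegf=(), svegfr1=(), ado=()):
    """Hand-built grid from coordinate lists; every EC gets birth cycle 0."""

    def layer(coords):
        arr = np.zeros((rows, cols), dtype=bool)
        for r, c in coords:
            arr[r, c] = True
        return arr

    return GridState.from_layers(
        layer(ec), layer(vegf), layer(svegfr1), layer(ado)
    )
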