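"""Output metrics of a finished simulation.

The model is quantified by two numbers: the *vessel network area* —
the final EC count as a fraction of the grid (numECs / gridArea) — and
the *network reach* — how far the network extends from the initial
vessel, i.e. the distance from the bottom row to the farthest tip,
a proxy for maximum branch length.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grid import GridState

__all__ = [
    "SimulationResult",
    "vessel_area",
    "network_reach",
    "network_reach_euclidean",
]


def vessel_area(grid: GridState) -> float:
    """Vessel network area: EC count divided by total grid sites.

    Depends on the EC layer only; always in [0, 1].
    """
    return grid.ec_count() / (grid.rows * grid.cols)


def network_reach(grid: GridState) -> int:
    """Network reach in site units: the maximum EC row index.

    Row 0 (the bottom row) holds the initial vessel, so the maximum row
    index is the vertical distance from the initial vessel to the
    farthest network tip. 0 means no outgrowth beyond the initial
    vessel.
    """
    rows_with_ec = np.nonzero(grid.ec.any(axis=1))[0]
    if len(rows_with_ec) == 0:
        raise ValueError("network_reach is undefined on an empty EC layer")
    return int(rows_with_ec[-1])


def network_reach_euclidean(grid: GridState) -> float:
    """Euclidean variant of reach: the largest distance from any EC to
    its nearest initial-vessel cell (birth cycle 0, bottom row).

    Provided as an alternative reading of "distance to the farthest
    tip"; the row-offset :func:`network_reach` is the default because
    the initial vessel spans the whole bottom row.
    """
    ec_r, ec_c = np.nonzero(grid.ec)
    if len(ec_r) == 0:
        raise ValueError("reach is undefined on an empty EC layer")
    seed_mask = (grid.ec_birth_cycle == 0) & grid.ec
    seed_mask[1:] = False  # the initial vessel lives in the bottom row
    seed_r, seed_c = np.nonzero(seed_mask)
    if len(seed_r) == 0:
        raise ValueError("no initial-vessel (birth cycle 0) ECs present")
    d2 = (ec_r[:, None] - seed_r[None, :]) ** 2 + (ec_c[:, None] - seed_c[None, :]) ** 2
    return float(np.sqrt(d2.min(axis=1).max()))


@dataclasses.dataclass
class SimulationResult:
    """Outcome of one simulation run.

    Attributes
    ----------
    final_grid
        Grid state after the last cycle.
    ec_series
        EC count per cycle, length ``num_cycles + 1`` (entry 0 is the
        initial count); non-decreasing.
    area
        Vessel network area of the final grid.
    reach
        Network reach of the final grid, in site units.
    seed
        Seed the run's random stream was created from.
    """

    final_grid: GridState
    ec_series: np.ndarray
    area: float
    reach: int
    seed: int

    @property
    def final_ec_count(self) -> int:
        return int(self.ec_series[-1])
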