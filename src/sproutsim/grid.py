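"""Lattice state: Boolean occupancy layers and initialization.

The spatial environment is an ``m x n`` lattice, the in-silico analogue
of a Matrigel well. Four Boolean layers record, per site, the presence
of an endothelial cell (EC), VEGF, sVEGFR-1 and adenosine. Row 0 is the
bottom of the grid and carries the initial vessel. Molecules may share a
site with each other and with ECs; within one layer occupancy is 0/1.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np

from .config import ConfigError, SimulationConfig

__all__ = ["Site", "GridState", "init_grid", "neighbour_sites"]

MOL_LAYERS = ("vegf", "svegfr1", "ado")


@dataclasses.dataclass(frozen=True)
class Site:
    """A lattice coordinate; ``row`` 0 is the bottom of the grid."""

    row: int
    col: int


@dataclasses.dataclass
class GridState:
    """Full lattice state at some cycle.

    Attributes
    ----------
    ec, vegf, svegfr1, ado
        Boolean ``(rows, cols)`` occupancy arrays.
    cycle
        Number of completed update cycles.
    ec_birth_cycle
        Integer ``(rows, cols)`` array; the cycle at which the EC at a
        site appeared (0 for the initial vessel), or -1 where no EC.
    """

    ec: np.ndarray
    vegf: np.ndarray
    svegfr1: np.ndarray
    ado: np.ndarray
    cycle: int
    ec_birth_cycle: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.ec.shape

    @property
    def rows(self) -> int:
        return self.ec.shape[0]

    @property
    def cols(self) -> int:
        return self.ec.shape[1]

    def ec_count(self) -> int:
        """Total number of endothelial cells on the grid (numECs)."""
        return int(self.ec.sum())

    def molecule_counts(self) -> dict[str, int]:
        return {name: int(getattr(self, name).sum()) for name in MOL_LAYERS}

    @property
    def _mol_counts(self) -> dict[str, int]:
        # Cached: per-layer counts are conserved by diffusion, so they are
        # computed once per state object (stale only if layers are hand-edited
        # after first use; build fresh states via from_layers instead).
        cached = self.__dict__.get("_mol_counts_cache")
        if cached is None:
            cached = self.molecule_counts()
            self.__dict__["_mol_counts_cache"] = cached
        return cached

    def copy(self) -> "GridState":
        return GridState(
            ec=self.ec.copy(),
            vegf=self.vegf.copy(),
            svegfr1=self.svegfr1.copy(),
            ado=self.ado.copy(),
            cycle=self.cycle,
            ec_birth_cycle=self.ec_birth_cycle.copy(),
        )

    @classmethod
    def from_layers(
        cls,
        ec: np.ndarray,
        vegf: np.ndarray | None = None,
        svegfr1: np.ndarray | None = None,
        ado: np.ndarray | None = None,
        cycle: int = 0,
    ) -> "GridState":
        """Build a state from hand-written Boolean layers (test fixtures).

        Every existing EC is stamped with birth cycle 0 so it is free to
        act in the first cycle run on the state.
        """
        ec = np.asarray(ec, dtype=bool)
        shape = ec.shape

        def layer(x):
            if x is None:
                return np.zeros(shape, dtype=bool)
            x = np.asarray(x, dtype=bool)
            if x.shape != shape:
                raise ValueError(f"layer shape {x.shape} != EC shape {shape}")
            return x

        birth = np.where(ec, 0, -1).astype(np.int32)
        return cls(
            ec=ec,
            vegf=layer(vegf),
            svegfr1=layer(svegfr1),
            ado=layer(ado),
            cycle=cycle,
            ec_birth_cycle=birth,
        )

    def __eq__(self, other: object) -> bool:  # value equality, for tests
        if not isinstance(other, GridState):
            return NotImplemented
        return (
            self.cycle == other.cycle
            and np.array_equal(self.ec, other.ec)
            and np.array_equal(self.vegf, other.vegf)
            and np.array_equal(self.svegfr1, other.svegfr1)
            and np.array_equal(self.ado, other.ado)
            and np.array_equal(self.ec_birth_cycle, other.ec_birth_cycle)
        )


def neighbour_sites(
    site: Site,
    rows: int,
    cols: int,
    offsets: tuple[tuple[int, int], ...] | None = None,
) -> list[Site]:
    """Neighbourhood of ``site`` clipped at the grid boundary.

    Defaults to the Moore neighbourhood (the 8 surrounding sites); never
    includes ``site`` itself; returned in row-major order of offsets.
    """
    if not (0 <= site.row < rows and 0 <= site.col < cols):
        raise ValueError(f"site {site} out of bounds for {rows}x{cols} grid")
    if offsets is None:
        from .config import MOORE

        offsets = MOORE
    out = []
    for dr, dc in offsets:
        r, c = site.row + dr, site.col + dc
        if 0 <= r < rows and 0 <= c < cols:
            out.append(Site(r, c))
    return out


def _scatter(
    rows: int, cols: int, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean layer with ``count`` sites occupied uniformly at random
    without replacement."""
    layer = np.zeros(rows * cols, dtype=bool)
    if count:
        idx = rng.choice(rows * cols, size=count, replace=False)
        layer[idx] = True
    return layer.reshape(rows, cols)


def init_grid(config: SimulationConfig, rng: np.random.Generator) -> GridState:
    """Initial lattice state for a run.

    The initial vessel is a contiguous, centered run of ``ini_ec`` ECs in
    the bottom row (ties broken toward lower column index). Each molecule
    layer receives its configured entity count uniformly at random
    without replacement, independently of the other layers.
    """
    rows, cols = config.rows, config.cols
    ec = np.zeros((rows, cols), dtype=bool)
    start = (cols - config.ini_ec) // 2
    ec[0, start : start + config.ini_ec] = True
    birth = np.where(ec, 0, -1).astype(np.int32)
    try:
        layers = {
            name: _scatter(rows, cols, getattr(config, f"n_{name}"), rng)
            for name in MOL_LAYERS
        }
    except ValueError as exc:  # count > capacity is already caught by config
        raise ConfigError(str(exc)) from exc
    return GridState(
        ec=ec,
        vegf=layers["vegf"],
        svegfr1=layers["svegfr1"],
        ado=layers["ado"],
        cycle=0,
        ec_birth_cycle=birth,
    )


def iter_ec_sites(grid: GridState) -> Iterator[Site]:
    """EC sites in row-major order."""
    for r, c in zip(*np.nonzero(grid.ec)):
        yield Site(int(r), int(c))
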