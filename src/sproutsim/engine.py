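"""Compiled simulation engine.

Runs whole simulations with numba-jitted per-cycle kernels. The engine
consumes the run's random stream in exactly the same order as the
reference operations in :mod:`sproutsim.rules` (see the protocol notes
there), so ``run_simulation(config, engine="fast")`` and
``engine="reference"`` return bit-identical results for the same
config — a property the test suite asserts on small grids.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import SimulationConfig
from .grid import MOL_LAYERS, GridState, init_grid
from .metrics import SimulationResult, network_reach, vessel_area
from .rules import run_cycle as _reference_cycle

__all__ = ["run_simulation", "run_cycles"]


@njit(cache=True)
def _ec_kernel(ec, birth, vegf, sv, ado, ar, ac, perm, u, p, use_ado,
               offr, offc, cur):
    """Division pass over the cycle-start ECs listed in (ar, ac).

    ``perm`` is the visit order; ``u`` holds two uniforms per visit
    (execution gate, daughter-site choice). Returns the number of
    daughters placed.
    """
    rows, cols = ec.shape
    noff = offr.shape[0]
    born = 0
    for i in range(perm.shape[0]):
        idx = perm[i]
        r = ar[idx]
        c = ac[idx]
        u_exec = u[2 * i]
        u_site = u[2 * i + 1]
        has_vegf = False
        has_sv = False
        has_ado = False
        for t in range(noff):
            rr = r + offr[t]
            cc = c + offc[t]
            if 0 <= rr < rows and 0 <= cc < cols:
                if vegf[rr, cc]:
                    has_vegf = True
                if sv[rr, cc]:
                    has_sv = True
                if ado[rr, cc]:
                    has_ado = True
        eligible = (has_vegf and not has_sv) or (use_ado and has_ado)
        if eligible and u_exec < p:
            nfree = 0
            for t in range(noff):
                rr = r + offr[t]
                cc = c + offc[t]
                if 0 <= rr < rows and 0 <= cc < cols and not ec[rr, cc]:
                    nfree += 1
            if nfree > 0:
                j = int(u_site * nfree)
                if j >= nfree:
                    j = nfree - 1
                seen = 0
                for t in range(noff):
                    rr = r + offr[t]
                    cc = c + offc[t]
                    if 0 <= rr < rows and 0 <= cc < cols and not ec[rr, cc]:
                        if seen == j:
                            ec[rr, cc] = True
                            birth[rr, cc] = cur
                            born += 1
                            break
                        seen += 1
    return born


@njit(cache=True)
def _diffuse_kernel(layer, lr, lc, perm, u, offr, offc):
    """Sequential diffusion pass over one molecule layer.

    Entities (row-major snapshot in ``lr``/``lc``) are processed in
    ``perm`` order; each draws a direction from its uniform in ``u`` and
    moves iff the target is in bounds and vacant in this layer.
    """
    rows, cols = layer.shape
    nd = offr.shape[0]
    for i in range(perm.shape[0]):
        idx = perm[i]
        d = int(u[i] * nd)
        if d >= nd:
            d = nd - 1
        r = lr[idx]
        c = lc[idx]
        rr = r + offr[d]
        cc = c + offc[d]
        if 0 <= rr < rows and 0 <= cc < cols and not layer[rr, cc]:
            layer[r, c] = False
            layer[rr, cc] = True
    return 0


def _offset_arrays(offsets) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(offsets, dtype=np.int64)
    return np.ascontiguousarray(arr[:, 0]), np.ascontiguousarray(arr[:, 1])


def _fast_cycle(grid: GridState, config: SimulationConfig,
                rng: np.random.Generator, ec_off, diff_off) -> int:
    """One compiled update cycle; returns daughters born."""
    actors = grid.ec & (grid.ec_birth_cycle <= grid.cycle)
    ar, ac = np.nonzero(actors)
    k = len(ar)
    born = 0
    if k:
        perm = rng.permutation(k)
        u = rng.random(2 * k)
        born = _ec_kernel(
            grid.ec, grid.ec_birth_cycle, grid.vegf, grid.svegfr1, grid.ado,
            ar, ac, perm, u, config.p_execute, config.ruleset == "R2",
            ec_off[0], ec_off[1], grid.cycle + 1,
        )
    for name in MOL_LAYERS:
        layer = getattr(grid, name)
        if not grid._mol_counts[name]:  # counts are conserved; skip empty layers
            continue
        lr, lc = np.nonzero(layer)
        n = len(lr)
        if n:
            perm = rng.permutation(n)
            u = rng.random(n)
            _diffuse_kernel(layer, lr, lc, perm, u, diff_off[0], diff_off[1])
    grid.cycle += 1
    return born


def run_cycles(
    grid: GridState,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_cycles: int,
    engine: str = "fast",
) -> list[int]:
    """Advance ``grid`` by ``n_cycles`` cycles; return the EC-count series
    after each cycle (length ``n_cycles``)."""
    series = []
    if engine == "fast":
        ec_off = _offset_arrays(config.ec_offsets())
        diff_off = _offset_arrays(config.diffusion_offsets())
        count = grid.ec_count()
        for _ in range(n_cycles):
            count += _fast_cycle(grid, config, rng, ec_off, diff_off)
            series.append(count)
    elif engine == "reference":
        for _ in range(n_cycles):
            _reference_cycle(grid, config, rng)
            series.append(grid.ec_count())
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return series


def run_simulation(config: SimulationConfig, engine: str = "fast") -> SimulationResult:
    """Run one full simulation from its own seeded random stream.

    Initializes the grid from ``config.seed``, advances ``num_cycles``
    cycles and returns the final grid together with the per-cycle EC
    count series and the derived metrics (vessel network area, network
    reach).

    ``engine="reference"`` runs the slow per-site reference loop from
    :mod:`sproutsim.rules` instead of the compiled kernels; both walk
    the random stream identically and give bit-identical results.
    """
    rng = np.random.default_rng(config.seed)
    grid = init_grid(config, rng)
    series = [grid.ec_count()]
    series.extend(run_cycles(grid, config, rng, config.num_cycles, engine=engine))
    # reach of an EC-free run (ini_ec = 0) is reported as 0: there is no
    # vessel to reach out from
    reach = network_reach(grid) if grid.ec_count() else 0
    return SimulationResult(
        final_grid=grid,
        ec_series=np.asarray(series, dtype=np.int64),
        area=vessel_area(grid),
        reach=reach,
        seed=config.seed,
    )
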