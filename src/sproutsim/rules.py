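"""Model rules: EC division eligibility, division, molecular diffusion.

These are the reference semantics of the model, written as plain,
readable per-site operations. :mod:`sproutsim.engine` provides a
compiled engine that reproduces them draw-for-draw on the same random
stream; the functions here are the ground truth it is tested against.

Random-stream protocol (shared with the engine)
-----------------------------------------------
All stochastic choices consume draws from a single ``numpy`` Generator
in a fixed order, independent of outcomes, so that two implementations
walking the same stream produce bit-identical states:

* :func:`attempt_division` always draws two uniforms (execution gate,
  daughter-site choice) per visited EC, whether or not it divides.
* :func:`diffuse` processes the layers in fixed order (VEGF, sVEGFR-1,
  Ado); per layer it snapshots entity positions in row-major order,
  draws one permutation of them, then one uniform per entity for the
  direction.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .grid import MOL_LAYERS, GridState, Site

__all__ = [
    "eligible_r1",
    "eligible_r2",
    "attempt_division",
    "diffuse",
    "run_cycle",
]


def _neighbourhood_flags(
    grid: GridState, site: Site, offsets
) -> tuple[bool, bool, bool]:
    """(any VEGF, any sVEGFR-1, any Ado) over the in-bounds neighbours."""
    rows, cols = grid.shape
    has_vegf = has_sv = has_ado = False
    for dr, dc in offsets:
        r, c = site.row + dr, site.col + dc
        if 0 <= r < rows and 0 <= c < cols:
            if grid.vegf[r, c]:
                has_vegf = True
            if grid.svegfr1[r, c]:
                has_sv = True
            if grid.ado[r, c]:
                has_ado = True
    return has_vegf, has_sv, has_ado


def _require_ec(grid: GridState, site: Site) -> None:
    if not (0 <= site.row < grid.rows and 0 <= site.col < grid.cols):
        raise ValueError(f"site {site} out of bounds")
    if not grid.ec[site.row, site.col]:
        raise ValueError(f"no EC at site {site}")


def eligible_r1(grid: GridState, site: Site, offsets=None) -> bool:
    """R1 division eligibility of the EC at ``site``.

    True iff at least one neighbour site carries VEGF and no neighbour
    site carries sVEGFR-1 (the soluble decoy receptor vetoes division).
    The EC's own site is not consulted. Pure predicate.
    """
    _require_ec(grid, site)
    if offsets is None:
        from .config import MOORE

        offsets = MOORE
    has_vegf, has_sv, _ = _neighbourhood_flags(grid, site, offsets)
    return has_vegf and not has_sv


def eligible_r2(grid: GridState, site: Site, offsets=None) -> bool:
    """R2 division eligibility: R1, or adenosine present nearby.

    Adenosine licenses division regardless of sVEGFR-1 — the modelled
    hypothesis that Ado both enhances VEGF activity and antagonizes the
    decoy receptor.
    """
    _require_ec(grid, site)
    if offsets is None:
        from .config import MOORE

        offsets = MOORE
    has_vegf, has_sv, has_ado = _neighbourhood_flags(grid, site, offsets)
    return (has_vegf and not has_sv) or has_ado


def attempt_division(
    grid: GridState,
    site: Site,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GridState:
    """One EC's stochastic division attempt; mutates ``grid`` in place.

    If the ruleset's eligibility predicate holds, the execution gate
    (uniform draw < ``p_execute``) passes, and at least one neighbour
    site is EC-free, exactly one EC-free neighbour chosen uniformly at
    random gains a daughter EC. The parent stays put (sprout extension);
    molecule layers are untouched (no consumption). Daughters are
    stamped with birth cycle ``grid.cycle + 1`` — the cycle currently
    being executed — and may act only from the following cycle.

    Two uniforms are always consumed from ``rng`` (see module notes).
    """
    _require_ec(grid, site)
    if grid.ec_birth_cycle[site.row, site.col] > grid.cycle:
        raise ValueError(
            f"EC at {site} was born this cycle and may not act before cycle "
            f"{grid.ec_birth_cycle[site.row, site.col] + 1}"
        )
    offsets = config.ec_offsets()
    if config.ruleset == "R2":
        ok = eligible_r2(grid, site, offsets)
    else:
        ok = eligible_r1(grid, site, offsets)
    u_exec = rng.random()
    u_site = rng.random()
    if not (ok and u_exec < config.p_execute):
        return grid
    rows, cols = grid.shape
    free = []
    for dr, dc in offsets:
        r, c = site.row + dr, site.col + dc
        if 0 <= r < rows and 0 <= c < cols and not grid.ec[r, c]:
            free.append((r, c))
    if not free:
        return grid
    j = min(int(u_site * len(free)), len(free) - 1)
    r, c = free[j]
    grid.ec[r, c] = True
    grid.ec_birth_cycle[r, c] = grid.cycle + 1
    return grid


def diffuse(
    grid: GridState,
    rng: np.random.Generator,
    offsets=None,
) -> GridState:
    """Stochastic diffusion of the molecular layers; mutates in place.

    Every VEGF, sVEGFR-1 and Ado entity picks one of its nearest
    (von Neumann) neighbour sites uniformly at random and moves there
    iff the target is in bounds and not already occupied by an entity
    of the same type — counting moves made earlier in this pass, which
    runs over the entities of each layer in a uniformly shuffled order.
    Blocked moves are aborted (the entity stays). Per-layer counts are
    conserved; the EC layer is untouched.
    """
    if offsets is None:
        from .config import VON_NEUMANN

        offsets = VON_NEUMANN
    rows, cols = grid.shape
    nd = len(offsets)
    for name in MOL_LAYERS:
        layer = getattr(grid, name)
        rs, cs = np.nonzero(layer)  # row-major snapshot
        n = len(rs)
        if n == 0:
            continue
        order = rng.permutation(n)
        for idx in order:
            u = rng.random()
            d = min(int(u * nd), nd - 1)
            r, c = int(rs[idx]), int(cs[idx])
            rr, cc = r + offsets[d][0], c + offsets[d][1]
            if 0 <= rr < rows and 0 <= cc < cols and not layer[rr, cc]:
                layer[r, c] = False
                layer[rr, cc] = True
    return grid


def run_cycle(
    grid: GridState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GridState:
    """One full update cycle; mutates ``grid`` in place.

    (1) Every EC present at cycle start (birth cycle <= ``grid.cycle``)
    is visited in a uniformly shuffled order and attempts division
    against the live grid; daughters born during the cycle are skipped,
    which caps sprout extension at one site per cycle per parent.
    (2) The molecular layers diffuse. (3) The cycle counter increments.
    """
    actors = grid.ec & (grid.ec_birth_cycle <= grid.cycle)
    rs, cs = np.nonzero(actors)  # row-major snapshot of cycle-start ECs
    k = len(rs)
    if k:
        order = rng.permutation(k)
        for idx in order:
            attempt_division(grid, Site(int(rs[idx]), int(cs[idx])), config, rng)
    diffuse(grid, rng, config.diffusion_offsets())
    grid.cycle += 1
    return grid
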