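"""Simulation configuration: parameters of a single model run.

A run is fully determined by a :class:`SimulationConfig`: lattice
dimensions, the number of entities of each type seeded onto the lattice,
the number of update cycles, the per-cycle rule-execution probability
``p_execute`` and the ruleset (``R1`` = VEGF activation vetoed by
sVEGFR-1; ``R2`` = R1 extended with adenosine override).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "CONTROL",
    "load_config",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates a model invariant."""


#: Moore neighbourhood (8 surrounding sites), row-major order.
MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
#: Von Neumann neighbourhood (4 orthogonally adjacent sites), row-major order.
VON_NEUMANN = ((-1, 0), (0, -1), (0, 1), (1, 0))

_NEIGHBOURHOODS = {"moore": MOORE, "von_neumann": VON_NEUMANN}


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All input parameters of one simulation run.

    Parameters
    ----------
    rows, cols
        Lattice dimensions; the grid has ``rows * cols`` sites. Row 0 is
        the *bottom* of the grid, where the initial vessel sits.
    ini_ec
        Length of the initial vessel: a contiguous, centered run of
        endothelial cells in the bottom row. Must fit (``ini_ec <= cols``).
    n_vegf, n_svegfr1, n_ado
        Number of VEGF / sVEGFR-1 / adenosine entities scattered uniformly
        over the grid at initialization. Occupancy is Boolean per layer,
        so each count is capped at ``rows * cols``; different entity types
        may share a site.
    num_cycles
        Number of update cycles (rule application over all EC sites,
        then molecular diffusion) per simulation.
    p_execute
        Probability that an eligible EC actually executes the division
        rule in a given cycle; encodes random motility / response
        heterogeneity.
    ruleset
        ``"R1"``: an EC may divide iff some neighbour site carries VEGF
        and no neighbour site carries sVEGFR-1. ``"R2"``: R1, or some
        neighbour site carries adenosine (which overrides sVEGFR-1).
    seed
        Seed for the run's private random stream.
    ec_neighbourhood, diffusion_neighbourhood
        Neighbourhood used for EC eligibility checks and daughter
        placement (default Moore, 8 sites) and for molecular diffusion
        (default von Neumann, the 4 nearest sites).
    """

    rows: int = 300
    cols: int = 300
    ini_ec: int = 300
    n_vegf: int = 0
    n_svegfr1: int = 0
    n_ado: int = 0
    num_cycles: int = 300
    p_execute: float = 0.05
    ruleset: str = "R1"
    seed: int = 0
    ec_neighbourhood: str = "moore"
    diffusion_neighbourhood: str = "von_neumann"

    def __post_init__(self) -> None:
        for name in ("rows", "cols", "num_cycles"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("ini_ec", "n_vegf", "n_svegfr1", "n_ado"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if self.ini_ec > self.cols:
            raise ConfigError(
                f"ini_ec={self.ini_ec} does not fit in the bottom row (cols={self.cols})"
            )
        capacity = self.rows * self.cols
        for name in ("n_vegf", "n_svegfr1", "n_ado"):
            v = getattr(self, name)
            if v > capacity:
                raise ConfigError(
                    f"{name}={v} exceeds grid capacity {capacity} "
                    "(Boolean occupancy: at most one entity of a type per site)"
                )
        if not 0.0 <= self.p_execute <= 1.0:
            raise ConfigError(f"p_execute must be in [0, 1], got {self.p_execute!r}")
        if self.ruleset not in ("R1", "R2"):
            raise ConfigError(f"ruleset must be 'R1' or 'R2', got {self.ruleset!r}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        for name in ("ec_neighbourhood", "diffusion_neighbourhood"):
            v = getattr(self, name)
            if v not in _NEIGHBOURHOODS:
                raise ConfigError(
                    f"{name} must be one of {sorted(_NEIGHBOURHOODS)}, got {v!r}"
                )

    @property
    def grid_area(self) -> int:
        """Total number of lattice sites (``rows * cols``)."""
        return self.rows * self.cols

    def ec_offsets(self) -> tuple[tuple[int, int], ...]:
        """Neighbourhood offsets used for EC rules and daughter placement."""
        return _NEIGHBOURHOODS[self.ec_neighbourhood]

    def diffusion_offsets(self) -> tuple[tuple[int, int], ...]:
        """Neighbourhood offsets used for molecular diffusion."""
        return _NEIGHBOURHOODS[self.diffusion_neighbourhood]

    def replace(self, **changes: Any) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


#: Calibrated control condition: VEGF/sVEGFR-1 at a 5:1 ratio on the
#: standard 300x300 grid, 300-cell initial vessel, 300 cycles, P=0.05.
CONTROL = SimulationConfig(
    rows=300, cols=300, ini_ec=300,
    n_vegf=40000, n_svegfr1=8000, n_ado=0,
    num_cycles=300, p_execute=0.05, ruleset="R1",
)

_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}
#: Keys accepted in config files beyond SimulationConfig fields (batch-level).
_EXTRA_KEYS = {"num_sim", "base_seed", "preset"}


def _parse_file(path: Path) -> dict[str, Any]:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path} must contain a flat key/value mapping")
    return dict(data)


def load_config(
    path: str | Path,
    overrides: Mapping[str, Any] | None = None,
) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a flat JSON or YAML file.

    ``overrides`` are applied after the file values. Unknown keys are
    rejected; batch-level keys (``num_sim``, ``base_seed``, ``preset``)
    are tolerated in the file but ignored here.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = _parse_file(path)
    for key, value in (overrides or {}).items():
        data[key] = value
    unknown = set(data) - _FIELD_NAMES - _EXTRA_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    fields = {k: v for k, v in data.items() if k in _FIELD_NAMES}
    return SimulationConfig(**fields)
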