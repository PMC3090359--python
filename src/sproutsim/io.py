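"""Deterministic serialization of grid states and run manifests.

Two plain-text formats are provided: a compact run-length JSON that
round-trips a :class:`~sproutsim.grid.GridState` exactly (all four
layers, the cycle counter and the EC birth-cycle array), and portable
graymap (PGM, P2) files for single layers — diff-able fixtures and
quick visual checks. PGM raster lines run top-to-bottom, so grid row 0
(the initial vessel) is written as the last raster line; reading flips
back, making the round-trip lossless.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np

from .config import SimulationConfig
from .grid import GridState

__all__ = [
    "grid_to_rle",
    "grid_from_rle",
    "save_grid",
    "load_grid",
    "write_pgm",
    "read_pgm",
    "RunManifest",
]


def _rle_encode(values: np.ndarray) -> list[list[int]]:
    """[value, run length] pairs over a flattened integer array."""
    flat = np.asarray(values).ravel()
    if flat.size == 0:
        return []
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flat.size]))
    return [[int(flat[s]), int(e - s)] for s, e in zip(starts, ends)]


def _rle_decode(pairs: list[list[int]], shape: tuple[int, int], dtype) -> np.ndarray:
    if pairs:
        flat = np.concatenate([np.full(n, v, dtype=dtype) for v, n in pairs])
    else:
        flat = np.empty(0, dtype=dtype)
    if flat.size != shape[0] * shape[1]:
        raise ValueError("run-length data does not match the stated shape")
    return flat.reshape(shape)


def grid_to_rle(grid: GridState) -> dict[str, Any]:
    """Exact, compact JSON-serializable representation of a state."""
    return {
        "format": "sproutsim-grid-rle",
        "version": 1,
        "rows": grid.rows,
        "cols": grid.cols,
        "cycle": grid.cycle,
        "layers": {
            name: _rle_encode(getattr(grid, name).astype(np.int8))
            for name in ("ec", "vegf", "svegfr1", "ado")
        },
        "ec_birth_cycle": _rle_encode(grid.ec_birth_cycle),
    }


def grid_from_rle(data: dict[str, Any]) -> GridState:
    if data.get("format") != "sproutsim-grid-rle":
        raise ValueError("not a sproutsim grid document")
    shape = (data["rows"], data["cols"])
    layers = {
        name: _rle_decode(data["layers"][name], shape, np.int8).astype(bool)
        for name in ("ec", "vegf", "svegfr1", "ado")
    }
    return GridState(
        ec=layers["ec"],
        vegf=layers["vegf"],
        svegfr1=layers["svegfr1"],
        ado=layers["ado"],
        cycle=int(data["cycle"]),
        ec_birth_cycle=_rle_decode(data["ec_birth_cycle"], shape, np.int32),
    )


def save_grid(grid: GridState, path: str | Path) -> None:
    Path(path).write_text(json.dumps(grid_to_rle(grid), separators=(",", ":")))


def load_grid(path: str | Path) -> GridState:
    return grid_from_rle(json.loads(Path(path).read_text()))


def write_pgm(layer: np.ndarray, path: str | Path, maxval: int = 1) -> None:
    """Write one layer as plain-text PGM (P2), grid row 0 at the image
    bottom (last raster line)."""
    arr = np.asarray(layer).astype(int)
    if arr.ndim != 2:
        raise ValueError("PGM export expects a 2-D layer")
    rows = np.flipud(arr)
    lines = ["P2", f"{arr.shape[1]} {arr.shape[0]}", str(maxval)]
    lines += [" ".join(str(v) for v in row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pgm(path: str | Path) -> np.ndarray:
    """Read a plain-text PGM (P2) written by :func:`write_pgm` back into
    grid orientation (row 0 = bottom)."""
    tokens: list[str] = []
    for line in Path(path).read_text().splitlines():
        body = line.split("#", 1)[0]
        tokens.extend(body.split())
    if not tokens or tokens[0] != "P2":
        raise ValueError(f"{path} is not a plain (P2) PGM file")
    width, height = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[4 : 4 + width * height], dtype=int)
    if data.size != width * height:
        raise ValueError("PGM pixel data truncated")
    return np.flipud(data.reshape(height, width))


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to experiment outputs."""

    config: dict[str, Any]
    preset: str | None
    base_seed: int
    tool_version: str
    timestamp: str
    outputs: dict[str, str]

    @classmethod
    def create(
        cls,
        config: SimulationConfig | dict[str, Any],
        base_seed: int,
        preset: str | None = None,
        outputs: dict[str, str] | None = None,
    ) -> "RunManifest":
        from . import __version__

        if isinstance(config, SimulationConfig):
            config = config.to_dict()
        return cls(
            config=config,
            preset=preset,
            base_seed=base_seed,
            tool_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            outputs=dict(outputs or {}),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
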