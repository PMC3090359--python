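"""Snapshot rendering of grid states.

One pixel per lattice site, grid row 0 (the initial vessel) at the
image bottom. ECs are drawn in a dedicated colour on top of optional
faint molecule-layer overlays. Output bytes are deterministic for a
given grid.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .grid import GridState

__all__ = ["render_snapshot", "snapshot_array"]

_BACKGROUND = (255, 255, 255)
_EC = (178, 24, 43)  # dark red
_OVERLAYS = {  # faint molecule tints
    "vegf": (225, 245, 225),
    "svegfr1": (225, 232, 245),
    "ado": (250, 244, 220),
}


def snapshot_array(
    grid: GridState,
    overlays: tuple[str, ...] = (),
    scale: int = 1,
) -> np.ndarray:
    """RGB uint8 image array of a state (row 0 rendered at the bottom)."""
    rows, cols = grid.shape
    img = np.empty((rows, cols, 3), dtype=np.uint8)
    img[:] = _BACKGROUND
    for name in overlays:
        if name not in _OVERLAYS:
            raise ValueError(f"unknown overlay layer {name!r}")
        img[np.asarray(getattr(grid, name), dtype=bool)] = _OVERLAYS[name]
    img[np.asarray(grid.ec, dtype=bool)] = _EC
    img = np.flipud(img)  # row 0 at the image bottom
    if scale > 1:
        img = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    return img


def render_snapshot(
    grid: GridState,
    path: str | Path,
    overlays: tuple[str, ...] = (),
    scale: int = 1,
) -> Path:
    """Write a PNG snapshot of ``grid`` to ``path``; returns the path."""
    path = Path(path)
    Image.fromarray(snapshot_array(grid, overlays=overlays, scale=scale)).save(
        path, format="PNG"
    )
    return path
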