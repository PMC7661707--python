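"""Minkowski functionals (area, perimeter, Euler number) over threshold sweeps.

N thresholds are spaced equally across the intensity range inside the mask
(both endpoints included). Each binary object is ``mask & (image >= t)``;
the mask exterior counts as background. Perimeter is the integer count of
4-neighbor foreground/background pixel edges; Euler number is 8-connected
objects minus 4-connected holes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class MinkowskiConfig:
    n_levels: int = 16

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")

    @property
    def feature_names(self) -> list[str]:
        N = self.n_levels
        return ([f"Area{i}" for i in range(1, N + 1)]
                + [f"Perimeter{i}" for i in range(1, N + 1)]
                + [f"Euler{i}" for i in range(1, N + 1)])


def binary_area(b: np.ndarray) -> int:
    return int(b.sum())


def binary_perimeter(b: np.ndarray) -> int:
    """Count of 4-neighbor edges between foreground and background.

    Pixels beyond the array border count as background, so an isolated
    pixel has perimeter 4.
    """
    b = np.asarray(b, dtype=bool)
    p = np.pad(b, 1, constant_values=False)
    edges = 0
    for shift in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        edges += int((p & ~np.roll(p, shift, axis=(0, 1))).sum())
    return edges


def binary_euler(b: np.ndarray) -> int:
    """Euler number: 8-connected objects minus 4-connected holes."""
    b = np.asarray(b, dtype=bool)
    _, n_objects = ndimage.label(b, structure=_STRUCT8)
    # holes: background components (4-connected) not reaching the exterior
    p = np.pad(b, 1, constant_values=False)
    lab, n_bg = ndimage.label(~p, structure=_STRUCT4)
    exterior = lab[0, 0]
    n_holes = n_bg - (1 if exterior > 0 else 0)
    return int(n_objects - n_holes)


def minkowski_features(image: np.ndarray, mask: np.ndarray,
                       config: MinkowskiConfig | None = None) -> dict[str, float]:
    """3N functional values of the N thresholded binaries of a masked image."""
    config = config or MinkowskiConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(image, dtype=float)[mask]
    lo, hi = vals.min(), vals.max()
    N = config.n_levels
    thresholds = np.linspace(lo, hi, N) if N > 1 else np.array([lo])
    areas, perims, eulers = [], [], []
    for t in thresholds:
        b = mask & (np.asarray(image, dtype=float) >= t)
        areas.append(binary_area(b))
        perims.append(binary_perimeter(b))
        eulers.append(binary_euler(b))
    out: dict[str, float] = {}
    for i in range(N):
        out[f"Area{i + 1}"] = float(areas[i])
    for i in range(N):
        out[f"Perimeter{i + 1}"] = float(perims[i])
    for i in range(N):
        out[f"Euler{i + 1}"] = float(eulers[i])
    return out
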