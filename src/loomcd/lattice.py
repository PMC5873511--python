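"""Integer-lattice neighbourhood helpers shared by the excitatory and
inhibitory layers.

Conventions: element coordinates are ``(col, row)`` with row 0 at the top of
the image; an offset ``(dx, dy)`` therefore points right for ``dx > 0`` and
down for ``dy > 0``.  Arrays are indexed ``[row, col]``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "disk_offsets",
    "offsets_to_kernel",
    "neighbourhood_sum",
    "disk_count",
]


def disk_offsets(radius: float, include_center: bool = True) -> list[tuple[int, int]]:
    """All lattice offsets ``(dx, dy)`` with Euclidean length <= *radius*."""
    r = int(np.floor(radius))
    out = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dx == 0 and dy == 0 and not include_center:
                continue
            if dx * dx + dy * dy <= radius * radius:
                out.append((dx, dy))
    return out


def offsets_to_kernel(
    offsets: list[tuple[int, int]],
    weights: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Build a correlation kernel that sums (weighted) neighbour values.

    The kernel is laid out so that ``scipy.ndimage.correlate(x, k)`` at
    element ``p`` sums ``w * x[p + (dy, dx)]`` over the offsets.
    """
    if not offsets:
        raise ValueError("offset list is empty")
    r = max(max(abs(dx), abs(dy)) for dx, dy in offsets)
    k = np.zeros((2 * r + 1, 2 * r + 1), dtype=float)
    if weights is None:
        weights = np.ones(len(offsets))
    for (dx, dy), w in zip(offsets, weights):
        k[r + dy, r + dx] = w
    return k


def neighbourhood_sum(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Weighted neighbourhood sum with the frame border clipped (no wrap)."""
    return ndimage.correlate(values.astype(float), kernel, mode="constant", cval=0.0)


def disk_count(mask: np.ndarray, radius: float, include_center: bool = True) -> np.ndarray:
    """Per-element count of True elements within Euclidean *radius*."""
    kernel = offsets_to_kernel(disk_offsets(radius, include_center))
    counts = neighbourhood_sum(mask.astype(float), kernel)
    return np.rint(counts).astype(int)
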