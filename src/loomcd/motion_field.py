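"""Local motion vectors, whole-field coherence, and shadow suppression.

Comparing the number of active elements across the four direction-selective
layers within a small circle yields a local motion direction at 45-degree
precision.  Two artifact filters are built on this field: a coherence check
that suspends the collision-risk output when most vectors agree (camera
shake / self-motion), and a ground-shadow classifier that silences elements
in the lower half of the danger zone whose vectors point towards the lower
frame border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .danger_zone import DangerZone
from .direction_nets import DIRECTION_DEGREES, DIRECTIONS, InhibitoryLayer
from .excitation import ExcitatoryState
from .lattice import disk_count

__all__ = [
    "MotionVectorField",
    "local_motion_vectors",
    "coherence_check",
    "shadow_suppression",
    "DOWNWARD_DEGREES",
]

#: Directions "towards the lower border with +/-45 degree precision"
#: (screen coordinates, 270 = straight down).
DOWNWARD_DEGREES = (225, 270, 315)

_ALL_DEGREES = np.arange(0, 360, 45)


@dataclass
class MotionVectorField:
    """Per-element motion directions at 45-degree precision.

    ``directions`` holds degrees in {0, 45, ..., 315} or -1 where no vector
    could be determined.
    """

    directions: np.ndarray  # int, shape (height, width); -1 = undetermined
    coherence_fraction: float = 0.0
    shadow_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.shadow_mask is None:
            self.shadow_mask = np.zeros(self.directions.shape, dtype=bool)

    @property
    def has_vector(self) -> np.ndarray:
        return self.directions >= 0


def _bisector(deg_a: int, deg_b: int) -> int:
    za = np.exp(1j * np.deg2rad(deg_a))
    zb = np.exp(1j * np.deg2rad(deg_b))
    ang = np.rad2deg(np.angle(za + zb)) % 360.0
    return int(np.rint(ang / 45.0) * 45) % 360


def local_motion_vectors(
    layers: dict[str, InhibitoryLayer],
    radius: float = 3.0,
    min_excited: int = 9,
    dominance_margin: int = 4,
    active_level: float = 0.1,
) -> MotionVectorField:
    """Derive a local motion direction per element from the four layers.

    For each element, active inhibitory elements (i > *active_level*) are
    counted per layer within a circle of *radius*.  A vector exists only if
    the total count strictly exceeds *min_excited*.  If one layer's count
    strictly exceeds every other layer's by more than *dominance_margin*,
    its preferred direction wins; if exactly two layers exceed the remaining
    ones and their preferred directions are 90 degrees apart, the bisecting
    diagonal wins; otherwise (including opposed 180-degree dominance) no
    vector is assigned.
    """
    counts = np.stack(
        [disk_count(layers[d].i_potentials > active_level, radius) for d in DIRECTIONS]
    )
    degs = np.array([DIRECTION_DEGREES[d] for d in DIRECTIONS])

    total = counts.sum(axis=0)
    has = total > min_excited

    order = np.argsort(counts, axis=0, kind="stable")
    csort = np.take_along_axis(counts, order, axis=0)
    c1, c2, c3 = csort[3], csort[2], csort[1]
    top1, top2 = order[3], order[2]

    single = c1 > c2 + dominance_margin
    pair = (~single) & (c1 > c3 + dominance_margin) & (c2 > c3 + dominance_margin)

    d1 = degs[top1]
    d2 = degs[top2]
    sep = np.abs(d1 - d2) % 360
    perpendicular = (sep == 90) | (sep == 270)

    directions = np.full(counts.shape[1:], -1, dtype=int)
    directions[has & single] = d1[has & single]

    diag = has & pair & perpendicular
    if diag.any():
        # quantized bisector of the two dominating preferred directions
        lut = {}
        for a in _ALL_DEGREES[::2]:
            for b in _ALL_DEGREES[::2]:
                if (a - b) % 360 in (90, 270):
                    lut[(a, b)] = _bisector(int(a), int(b))
        flat = directions[diag]
        for idx, (a, b) in enumerate(zip(d1[diag].ravel(), d2[diag].ravel())):
            flat[idx] = lut[(int(a), int(b))]
        directions[diag] = flat
    return MotionVectorField(directions=directions)


def coherence_check(
    field: MotionVectorField, limit: float = 0.5
) -> tuple[bool, float]:
    """Whole-field coherent-motion test over all vector-bearing elements.

    For each of the eight directions, the fraction of vectors lying within
    +/-45 degrees of it is computed; the flag is raised iff the maximum
    fraction strictly exceeds *limit*.  A field with no vectors never flags.
    Returns (flag, max fraction); the fraction is stored on the field.
    """
    dirs = field.directions[field.has_vector]
    if dirs.size == 0:
        field.coherence_fraction = 0.0
        return False, 0.0
    best = 0.0
    for center in _ALL_DEGREES:
        delta = np.abs((dirs - center + 180) % 360 - 180)
        best = max(best, float((delta <= 45).mean()))
    field.coherence_fraction = best
    return best > limit, best


def shadow_suppression(
    field: MotionVectorField,
    zone: DangerZone,
    e_layer: ExcitatoryState,
    layers: dict[str, InhibitoryLayer],
    fraction: float = 0.2,
) -> tuple[np.ndarray, ExcitatoryState]:
    """Classify and silence ground-shadow elements (modifies layers in place).

    If strictly more than *fraction* of the elements in the lower half of
    the danger zone carry a motion vector pointing towards the lower frame
    border (+/-45 degrees), every such element is flagged as shadow and its
    e-potential and all four i-potentials are set to zero before the risk
    and steering sums of this step.  Returns (shadow mask, new e-layer).
    """
    lower = zone.lower_half
    denom = int(lower.sum())
    downward = np.isin(field.directions, DOWNWARD_DEGREES)
    shadow = lower & downward
    if denom == 0 or shadow.sum() / denom <= fraction:
        field.shadow_mask = np.zeros_like(lower)
        return field.shadow_mask, e_layer
    field.shadow_mask = shadow
    from dataclasses import replace

    e_new = replace(
        e_layer, e_potentials=np.where(shadow, 0.0, e_layer.e_potentials)
    )
    for layer in layers.values():
        layer.i_potentials = np.where(shadow, 0.0, layer.i_potentials)
    return shadow, e_new
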