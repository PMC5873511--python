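"""Four direction-selective layers with delayed, decaying lateral inhibition.

Each layer receives the excitatory e-potentials and subtracts, per element,
a distance-weighted sum of the *previous* step's e-potentials sampled from
11 elements in a hemicircle on one side of the focal element.  The one-step
delay makes each layer an elementary-motion-detector array: motion in the
preferred direction escapes the inhibition that trails behind it, motion in
the null direction runs into it.  Inhibition, once stored, decays linearly
over processing steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .danger_zone import DangerZone
from .excitation import ExcitatoryState
from .lattice import neighbourhood_sum, offsets_to_kernel

__all__ = [
    "DIRECTIONS",
    "DIRECTION_DEGREES",
    "InhibitoryLayer",
    "LayerExcitation",
    "hemicircle_offsets",
    "distance_weighted_inhibition",
    "decay_inhibition",
    "update_i_potentials",
    "layer_excitation",
    "make_layers",
]

#: Layer order used throughout the package.
DIRECTIONS = ("right", "left", "up", "down")

#: Preferred direction of each layer in degrees; 0 = rightward, 90 = upward
#: (towards the top border), 270 = downward (screen coordinates).
DIRECTION_DEGREES = {"right": 0, "up": 90, "left": 180, "down": 270}


def _rot90(offsets: list[tuple[int, int]]) -> list[tuple[int, int]]:
    # one visual quarter turn: right -> up -> left -> down (y grows downward)
    return [(dy, -dx) for dx, dy in offsets]


def hemicircle_offsets(direction: str, radius: float = 3.0) -> list[tuple[int, int]]:
    """Lattice offsets of the inhibitory hemicircle for one layer.

    For the rightward-preferring layer the inhibitors lie strictly to the
    right of the focal element: all offsets ``(dx, dy)`` with ``dx >= 1`` and
    Euclidean length <= *radius* (exactly 11 offsets at radius 3).  The other
    layers are exact quarter-turn rotations of this set, which guarantees
    the 90-degree equivariance of the network.
    """
    r = int(np.floor(radius))
    right = [
        (dx, dy)
        for dx in range(1, r + 1)
        for dy in range(-r, r + 1)
        if dx * dx + dy * dy <= radius * radius
    ]
    turns = {"right": 0, "up": 1, "left": 2, "down": 3}
    if direction not in turns:
        raise ValueError(f"unknown direction {direction!r}")
    out = right
    for _ in range(turns[direction]):
        out = _rot90(out)
    return out


@dataclass
class InhibitoryLayer:
    """State of one direction-selective inhibitory layer.

    ``stored_inhibition`` holds the last saved distance-weighted inhibition
    value per element and ``decay_counter`` the number of processing steps
    since it was saved; the effective inhibition decays by ``decay_step``
    times the counter.
    """

    preferred_direction: str
    i_potentials: np.ndarray
    stored_inhibition: np.ndarray
    decay_counter: np.ndarray
    inhibition_weight: float = 0.35
    reset_threshold: float = 1.5
    radius: float = 3.0
    decay_step: float = 2.0
    _kernel: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        offsets = hemicircle_offsets(self.preferred_direction, self.radius)
        weights = [self.inhibition_weight / np.hypot(dx, dy) for dx, dy in offsets]
        self._kernel = offsets_to_kernel(offsets, weights)

    @property
    def offsets(self) -> list[tuple[int, int]]:
        return hemicircle_offsets(self.preferred_direction, self.radius)


@dataclass
class LayerExcitation:
    """Zone-restricted excitation of one layer (input to steering)."""

    value: float
    m: int
    s: int


def make_layers(
    shape: tuple[int, int],
    inhibition_weight: float = 0.35,
    reset_threshold: float = 1.5,
    radius: float = 3.0,
    decay_step: float = 2.0,
) -> dict[str, InhibitoryLayer]:
    """Fresh all-zero layers for the four preferred directions."""
    return {
        d: InhibitoryLayer(
            preferred_direction=d,
            i_potentials=np.zeros(shape),
            stored_inhibition=np.zeros(shape),
            decay_counter=np.zeros(shape, dtype=int),
            inhibition_weight=inhibition_weight,
            reset_threshold=reset_threshold,
            radius=radius,
            decay_step=decay_step,
        )
        for d in DIRECTIONS
    }


def distance_weighted_inhibition(
    e_layer: ExcitatoryState | np.ndarray, layer: InhibitoryLayer
) -> np.ndarray:
    """Distance-weighted inhibitory drive sampled from an e-layer.

    Per element: ``weight * sum over hemicircle offsets of E_k / d_k`` where
    ``d_k`` is the offset's Euclidean length; offsets falling outside the
    frame contribute 0.  The one-processing-step delay of the lateral
    inhibition arises from the save-and-apply bookkeeping: the value
    computed from the current step's (thresholded, cluster-filtered)
    e-layer is stored and only subtracted from e-potentials of subsequent
    steps, via :func:`decay_inhibition`.
    """
    e = e_layer.e_potentials if isinstance(e_layer, ExcitatoryState) else np.asarray(e_layer, float)
    return neighbourhood_sum(e, layer._kernel)


def decay_inhibition(layer: InhibitoryLayer) -> np.ndarray:
    """Decayed inhibition: stored value minus decay_step * counter, floored at 0."""
    return np.maximum(
        layer.stored_inhibition - layer.decay_step * layer.decay_counter, 0.0
    )


def update_i_potentials(
    e_now: ExcitatoryState | np.ndarray,
    layer: InhibitoryLayer,
    i_dist: np.ndarray | None = None,
) -> InhibitoryLayer:
    """One processing step of a layer (in place; returns the layer).

    The i-potential is the current e-potential minus the decayed stored
    inhibition, clamped at 0 — so excitation saved at step t first inhibits
    at step t+1 (the one-step delay of the lateral inhibition network).
    Where the fresh distance-weighted inhibition (sampled from the current
    e-layer) exceeds the decayed value by more than ``reset_threshold``, it
    is saved and the decay counter restarts; elsewhere the counter advances
    by one step.
    """
    e = e_now.e_potentials if isinstance(e_now, ExcitatoryState) else np.asarray(e_now, float)
    if i_dist is None:
        i_dist = distance_weighted_inhibition(e, layer)
    i_decay = decay_inhibition(layer)
    layer.i_potentials = np.maximum(e - i_decay, 0.0)
    reset = i_dist > i_decay + layer.reset_threshold
    layer.stored_inhibition = np.where(reset, i_dist, layer.stored_inhibition)
    layer.decay_counter = np.where(reset, 0, layer.decay_counter + 1)
    return layer


def layer_excitation(
    layer: InhibitoryLayer,
    zone: DangerZone,
    active_level: float = 0.1,
    strong_level: float = 1.0,
) -> LayerExcitation:
    """Zone excitation of one layer: sum of i-potentials > *active_level*
    over zone members, weighted by m/s with m the count of members whose
    i-potential exceeds *strong_level*."""
    i = layer.i_potentials
    active = zone.mask & (i > active_level)
    m = int((zone.mask & (i > strong_level)).sum())
    value = (m / zone.s) * float(i[active].sum())
    return LayerExcitation(value=value, m=m, s=zone.s)
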