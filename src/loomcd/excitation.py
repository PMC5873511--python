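"""Excitatory layer: second-order frame differencing, thresholding and the
cluster rule.

Motion is quantified per element as the absolute difference between the
luminance changes of successive frame pairs (a second-order temporal
difference).  This cancels any uniform, constant-rate illumination drift and
responds to *changes* in local luminance change — the accelerating edge
signature of an approaching object.  The resulting "e-potentials" must
exceed a film-level threshold and pass a primitive object-recognition
(cluster) rule before contributing to the collision risk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError
from .frames_io import FrameGrid
from .lattice import disk_count

__all__ = [
    "ExcitatoryState",
    "pair_difference",
    "update_e_potentials",
    "apply_threshold",
    "cluster_filter",
]


@dataclass
class ExcitatoryState:
    """Per-element e-potentials plus the retained previous frame-pair difference.

    ``prev_pair_diff`` holds ``|frame(N-1) - frame(N-2)|`` so that the next
    update can take the second-order difference; it is all-zero before the
    second frame pair exists (warm-up).
    """

    e_potentials: np.ndarray
    prev_pair_diff: np.ndarray
    e_threshold: float

    @classmethod
    def initial(cls, shape: tuple[int, int], e_threshold: float) -> "ExcitatoryState":
        return cls(np.zeros(shape), np.zeros(shape), float(e_threshold))


def _values(frame: FrameGrid | np.ndarray) -> np.ndarray:
    return frame.values if isinstance(frame, FrameGrid) else np.asarray(frame, float)


def pair_difference(
    frame_n: FrameGrid | np.ndarray, frame_n_minus_1: FrameGrid | np.ndarray
) -> np.ndarray:
    """Element-wise absolute luminance change between consecutive frames."""
    a, b = _values(frame_n), _values(frame_n_minus_1)
    if a.shape != b.shape:
        raise InputError(f"frame shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def update_e_potentials(state: ExcitatoryState, pair_diff: np.ndarray) -> ExcitatoryState:
    """Second-order differencing: e = |pair_diff - previous pair_diff|.

    Returns a new state with the pair difference rolled forward.
    """
    pair_diff = np.asarray(pair_diff, float)
    if pair_diff.shape != state.prev_pair_diff.shape:
        raise InputError("pair_diff shape does not match state")
    e = np.abs(pair_diff - state.prev_pair_diff)
    return replace(state, e_potentials=e, prev_pair_diff=pair_diff.copy())


def apply_threshold(state: ExcitatoryState) -> ExcitatoryState:
    """Zero every e-potential that does not strictly exceed the threshold."""
    e = np.where(state.e_potentials > state.e_threshold, state.e_potentials, 0.0)
    return replace(state, e_potentials=e)


def cluster_filter(
    state: ExcitatoryState, radius: float = 3.0, min_count: int = 10
) -> ExcitatoryState:
    """Primitive object recognition: remove isolated excitation.

    An excited element keeps its e-potential only if more than *min_count*
    excited elements lie within a circle of *radius* elements (Euclidean
    distance on the lattice, focal element included in the count).  Counts
    are taken against the pre-filter layer, so the result does not depend on
    a sweep order.  Small or elongated (< 2-element wide) patches of
    excitation are thereby rejected.
    """
    excited = state.e_potentials > 0
    counts = disk_count(excited, radius, include_center=True)
    keep = excited & (counts > min_count)
    return replace(state, e_potentials=np.where(keep, state.e_potentials, 0.0))
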