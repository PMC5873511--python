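"""Danger zone geometry and the per-frame collision-risk terms.

The danger zone is a circular image region centred where a frontal collision
would appear, intersected with the middle band of the frame: the lower
quarter of the frame is excluded to avoid ground shadows and lane markings,
the upper quarter to avoid bridges and overhead signs.  All risk and
steering sums are restricted to the zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .excitation import ExcitatoryState

__all__ = [
    "DangerZone",
    "RiskResult",
    "build_zone",
    "r_coll",
    "r_dist",
    "overstimulation_check",
    "combine_risk",
]


@dataclass(frozen=True)
class DangerZone:
    """Circular danger zone minus the horizontal exclusion bands.

    Membership is enumerated once (as a boolean mask over the element
    lattice) and reused for every frame of a run.
    """

    center: tuple[float, float]  # (col, row)
    radius: float
    mask: np.ndarray  # bool, shape (height, width)
    distances: np.ndarray  # Euclidean distance of each element to the center
    top_exclusion: float
    bottom_exclusion: float
    s: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", int(self.mask.sum()))

    @property
    def lower_half(self) -> np.ndarray:
        """Members strictly below the zone center's row."""
        rows = np.arange(self.mask.shape[0])[:, None]
        return self.mask & (rows > self.center[1])


@dataclass
class RiskResult:
    """Per-frame collision-risk decomposition."""

    r_coll: float
    r_dist: float
    n_qualifying: int
    total_risk: float
    suspended: bool
    suspension_reason: str | None
    w: int


def build_zone(
    frame_shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    radius: float = 50.0,
    top_exclusion: float = 0.25,
    bottom_exclusion: float = 0.25,
) -> DangerZone:
    """Enumerate zone membership for a frame of shape ``(height, width)``.

    An element (col, row) is a member iff its Euclidean distance to *center*
    is <= *radius* and its row lies inside the non-excluded horizontal band
    ``[top_exclusion * H, (1 - bottom_exclusion) * H]`` of the full frame.
    """
    h, w = frame_shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    cols = np.arange(w)[None, :]
    rows = np.arange(h)[:, None]
    distances = np.hypot(cols - cx, rows - cy)
    in_band = (rows >= top_exclusion * h) & (rows <= (1.0 - bottom_exclusion) * h)
    mask = (distances <= radius) & in_band
    if not mask.any():
        raise ConfigError(
            f"danger zone (center {center}, radius {radius}) has no members "
            f"inside the non-excluded band of a {h}x{w} frame"
        )
    return DangerZone(
        center=(float(cx), float(cy)),
        radius=float(radius),
        mask=mask,
        distances=distances,
        top_exclusion=top_exclusion,
        bottom_exclusion=bottom_exclusion,
    )


def r_coll(e_layer: ExcitatoryState, zone: DangerZone) -> tuple[float, int]:
    """First risk term: zone sum of supra-threshold e-potentials times w/s.

    The e-layer must already be thresholded and cluster-filtered, so every
    nonzero member exceeds the threshold; *w* counts those members and the
    weight ``w / s`` mirrors the relative excitation of the zone.
    """
    e = e_layer.e_potentials
    member = zone.mask & (e > 0)
    w = int(member.sum())
    total = float(e[member].sum())
    return (w / zone.s) * total, w


def r_dist(
    e_layer: ExcitatoryState,
    zone: DangerZone,
    gain: float = 10.0,
    qualify_level: float = 0.5,
) -> tuple[float, int]:
    """Second risk term: inverse-distance bonus for excitation near the center.

    Sums ``gain / d_k`` over zone members whose e-potential exceeds
    ``qualify_level`` (on the thresholded layer this is equivalent to
    exceeding both the film threshold and the fixed 0.5 level) and whose
    distance to the zone center satisfies ``0 < d_k < radius / 2``.  Elements
    exactly at the center are excluded.  Returns (value, N).
    """
    e = e_layer.e_potentials
    qual = (
        zone.mask
        & (e > qualify_level)
        & (zone.distances > 0)
        & (zone.distances < zone.radius / 2.0)
    )
    n = int(qual.sum())
    value = gain * float((1.0 / zone.distances[qual]).sum()) if n else 0.0
    return value, n


def overstimulation_check(
    e_layer: ExcitatoryState,
    zone: DangerZone,
    level: float = 0.5,
    fraction: float = 0.40,
) -> bool:
    """True iff strictly more than *fraction* of zone members have e > *level*."""
    excited = int((zone.mask & (e_layer.e_potentials > level)).sum())
    return excited / zone.s > fraction


def combine_risk(
    r_coll_value: float,
    r_dist_value: float,
    n_qualifying: int,
    w: int = 0,
    suspension_reason: str | None = None,
    n_min: int = 15,
) -> RiskResult:
    """Total risk: r_coll, plus r_dist when strictly more than *n_min* elements
    qualify; forced to 0 when a suspension rule fired."""
    total = r_coll_value + (r_dist_value if n_qualifying > n_min else 0.0)
    suspended = suspension_reason is not None
    if suspended:
        total = 0.0
    if not np.isfinite(total):
        raise FloatingPointError("non-finite collision risk")
    return RiskResult(
        r_coll=r_coll_value,
        r_dist=r_dist_value,
        n_qualifying=n_qualifying,
        total_risk=total,
        suspended=suspended,
        suspension_reason=suspension_reason,
        w=w,
    )
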