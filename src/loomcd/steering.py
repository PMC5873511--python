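"""Evasive steering from the left/right layer-excitation difference.

Stronger excitation of the rightward-selective layer means the threatening
motion is on the right-hand side of the visual field, so the evasive
maneuver points left, and vice versa.  The difference must strictly exceed
a fixed threshold before a direction is committed; the raw absolute
difference is exported as a dimensionless steering force so downstream
controllers can apply their own gain.
"""

from __future__ import annotations

from dataclasses import dataclass

from .direction_nets import LayerExcitation

__all__ = ["SteeringDecision", "steering_vector"]


@dataclass
class SteeringDecision:
    direction: str | None  # None | "left" | "right"
    force: float
    threshold: float = 6.0


def steering_vector(
    exc_left: LayerExcitation,
    exc_right: LayerExcitation,
    threshold: float = 6.0,
) -> SteeringDecision:
    """Map the layer-excitation difference to an evasive steering decision.

    direction = left  iff E_right - E_left > threshold,
    direction = right iff E_left - E_right > threshold,
    otherwise none (ties and sub-threshold differences).
    """
    diff = exc_right.value - exc_left.value
    force = abs(diff)
    if diff > threshold:
        direction = "left"
    elif -diff > threshold:
        direction = "right"
    else:
        direction = None
    return SteeringDecision(direction=direction, force=force, threshold=threshold)
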