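"""Per-frame orchestration of the collision-detection network.

The canonical processing order per frame is: frame-pair difference →
second-order e-potentials → threshold → cluster filter → inhibitory-layer
update (current excitation minus the stored, decayed inhibition of earlier
steps) → local motion vectors → shadow suppression → coherence and
overstimulation checks → risk combination → steering.  The first two
frames of a sequence carry a warm-up flag (the second-order difference
needs three frames).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .danger_zone import (
    DangerZone,
    build_zone,
    combine_risk,
    overstimulation_check,
    r_coll,
    r_dist,
)
from .direction_nets import DIRECTIONS, layer_excitation, make_layers, distance_weighted_inhibition, update_i_potentials
from .errors import ConfigError, InputError
from .excitation import (
    ExcitatoryState,
    apply_threshold,
    cluster_filter,
    pair_difference,
    update_e_potentials,
)
from .frames_io import GREY_MAX, FrameGrid, image_contrast, threshold_from_contrast
from .motion_field import coherence_check, local_motion_vectors, shadow_suppression
from .steering import steering_vector

logger = logging.getLogger("loomcd")

__all__ = ["RunConfig", "FrameResult", "process_sequence", "results_to_dataframe", "render_overlay"]


@dataclass
class RunConfig:
    """Complete run configuration; every constant defaults to the published
    network parameters.  ``e_threshold=None`` derives the threshold from the
    contrast of the representative frame; an explicit value overrides it."""

    # danger zone
    zone_center: tuple[float, float] | None = None  # (col, row); None = frame center
    zone_radius: float = 50.0
    top_exclusion: float = 0.25
    bottom_exclusion: float = 0.25
    # excitation
    e_threshold: float | None = None
    representative_frame: int = 0
    cluster_radius: float = 3.0
    cluster_min_count: int = 10
    # risk
    dist_gain: float = 10.0
    dist_qualify_level: float = 0.5
    n_qualify_min: int = 15
    overstim_level: float = 0.5
    overstim_fraction: float = 0.40
    # inhibition
    inhibition_weight: float = 0.35
    reset_threshold: float = 1.5
    hemicircle_radius: float = 3.0
    decay_step: float = 2.0
    i_active_level: float = 0.1
    i_strong_level: float = 1.0
    # motion field / artifact suppression
    vector_circle_radius: float = 3.0
    vector_min_excited: int = 9
    dominance_margin: int = 4
    coherence_limit: float = 0.5
    shadow_fraction: float = 0.2
    suppress_shadows: bool = True
    suppress_coherent: bool = True
    # steering
    steering_threshold: float = 6.0

    def resolve_threshold(self, frames: list[FrameGrid]) -> float:
        if self.e_threshold is not None:
            return float(self.e_threshold)
        idx = self.representative_frame
        if not 0 <= idx < len(frames):
            raise ConfigError(f"representative frame {idx} outside sequence")
        return threshold_from_contrast(image_contrast(frames[idx]))


@dataclass
class FrameResult:
    """Per-frame outputs of the collision-detection network."""

    frame_index: int
    warm_up: bool
    r_coll: float = 0.0
    r_dist: float = 0.0
    n_qualifying: int = 0
    w: int = 0
    total_risk: float = 0.0
    suspended: bool = False
    suspension_reason: str | None = None
    steering_direction: str | None = None
    steering_force: float = 0.0
    coherence_fraction: float = 0.0
    n_shadow: int = 0
    exc_right: float = 0.0
    exc_left: float = 0.0
    exc_up: float = 0.0
    exc_down: float = 0.0


@dataclass
class FrameDetail:
    """Intermediate per-frame arrays, retained on request (overlays, tests)."""

    e_potentials: np.ndarray
    directions: np.ndarray
    shadow_mask: np.ndarray


def process_sequence(
    frames: list[FrameGrid] | list[np.ndarray],
    config: RunConfig | None = None,
    keep_detail: bool = False,
):
    """Run the collision-detection network over an ordered frame sequence.

    Returns a list of :class:`FrameResult`, or ``(results, details, zone)``
    when *keep_detail* is true.  Deterministic: identical input and config
    give bit-identical output.
    """
    config = config or RunConfig()
    frames = [f if isinstance(f, FrameGrid) else FrameGrid(f, k) for k, f in enumerate(frames)]
    if len(frames) < 3:
        raise InputError("need at least 3 frames (second-order differencing)")
    shape = frames[0].values.shape
    if any(f.values.shape != shape for f in frames):
        raise InputError("frames differ in shape")

    zone = build_zone(
        shape,
        center=config.zone_center,
        radius=config.zone_radius,
        top_exclusion=config.top_exclusion,
        bottom_exclusion=config.bottom_exclusion,
    )
    e_threshold = config.resolve_threshold(frames)
    state = ExcitatoryState.initial(shape, e_threshold)
    layers = make_layers(
        shape,
        inhibition_weight=config.inhibition_weight,
        reset_threshold=config.reset_threshold,
        radius=config.hemicircle_radius,
        decay_step=config.decay_step,
    )

    results: list[FrameResult] = []
    details: list[FrameDetail | None] = []
    prev_frame = None
    for k, frame in enumerate(frames):
        if k < 2:
            # warm-up: no valid second-order difference yet
            if k == 1:
                state.prev_pair_diff = pair_difference(frame, prev_frame)
            prev_frame = frame
            results.append(FrameResult(frame_index=k, warm_up=True))
            details.append(None)
            continue

        pd_now = pair_difference(frame, prev_frame)
        prev_frame = frame
        state = update_e_potentials(state, pd_now)
        state = cluster_filter(
            apply_threshold(state), config.cluster_radius, config.cluster_min_count
        )

        # lateral inhibition: sampled from the current filtered e-layer,
        # stored, and applied with a one-step delay inside the layer update
        for d in DIRECTIONS:
            i_dist = distance_weighted_inhibition(state, layers[d])
            update_i_potentials(state, layers[d], i_dist)

        fieldv = local_motion_vectors(
            layers,
            radius=config.vector_circle_radius,
            min_excited=config.vector_min_excited,
            dominance_margin=config.dominance_margin,
            active_level=config.i_active_level,
        )

        if config.suppress_shadows:
            shadow_mask, state = shadow_suppression(
                fieldv, zone, state, layers, fraction=config.shadow_fraction
            )
        else:
            shadow_mask = np.zeros(shape, dtype=bool)

        coherent, coh_frac = coherence_check(fieldv, limit=config.coherence_limit)
        overstim = overstimulation_check(
            state, zone, level=config.overstim_level, fraction=config.overstim_fraction
        )
        reason = None
        if coherent and config.suppress_coherent:
            reason = "coherent_motion"
        elif overstim:
            reason = "overstimulation"

        rc, w = r_coll(state, zone)
        rd, n_qual = r_dist(
            state, zone, gain=config.dist_gain, qualify_level=config.dist_qualify_level
        )
        try:
            risk = combine_risk(rc, rd, n_qual, w, reason, n_min=config.n_qualify_min)
        except FloatingPointError as exc:
            raise FloatingPointError(f"frame {k}: {exc}") from exc

        excs = {
            d: layer_excitation(
                layers[d], zone, config.i_active_level, config.i_strong_level
            )
            for d in DIRECTIONS
        }
        steer = steering_vector(
            excs["left"], excs["right"], threshold=config.steering_threshold
        )
        # no actuation advice on suspended frames; the force stays reported
        # as a diagnostic
        direction = None if risk.suspended else steer.direction

        result = FrameResult(
            frame_index=k,
            warm_up=False,
            r_coll=rc,
            r_dist=rd,
            n_qualifying=n_qual,
            w=w,
            total_risk=risk.total_risk,
            suspended=risk.suspended,
            suspension_reason=risk.suspension_reason,
            steering_direction=direction,
            steering_force=steer.force,
            coherence_fraction=coh_frac,
            n_shadow=int(shadow_mask.sum()),
            exc_right=excs["right"].value,
            exc_left=excs["left"].value,
            exc_up=excs["up"].value,
            exc_down=excs["down"].value,
        )
        results.append(result)
        details.append(
            FrameDetail(
                e_potentials=state.e_potentials.copy(),
                directions=fieldv.directions.copy(),
                shadow_mask=shadow_mask.copy(),
            )
        )
        logger.debug(
            "frame %d risk=%.3f (r_coll=%.3f r_dist=%.3f N=%d w=%d) "
            "suspended=%s reason=%s steer=%s force=%.3f coherence=%.3f shadows=%d",
            k, risk.total_risk, rc, rd, n_qual, w, risk.suspended, reason,
            direction, steer.force, coh_frac, int(shadow_mask.sum()),
        )


    if keep_detail:
        return results, details, zone
    return results


def results_to_dataframe(results: list[FrameResult]) -> pd.DataFrame:
    """One row per frame; round-trips losslessly through CSV."""
    return pd.DataFrame([asdict(r) for r in results])


def _draw_circle(img: np.ndarray, center, radius, color) -> None:
    h, w = img.shape[:2]
    cx, cy = center
    theta = np.linspace(0, 2 * np.pi, int(8 * radius) + 16)
    cols = np.clip(np.rint(cx + radius * np.cos(theta)).astype(int), 0, w - 1)
    rows = np.clip(np.rint(cy + radius * np.sin(theta)).astype(int), 0, h - 1)
    img[rows, cols] = color


def render_overlay(
    frames: list[FrameGrid],
    results: list[FrameResult],
    details: list,
    zone: DangerZone,
    outdir=None,
    draw_zone: bool = True,
    draw_vectors: bool = True,
    vector_stride: int = 4,
) -> list[np.ndarray]:
    """Annotate frames: excited elements tinted red, shadow elements yellow,
    the danger-zone circle in blue, local motion vectors and the steering
    arrow in green.  Returns RGB uint8 arrays; writes numbered PNGs when
    *outdir* is given."""
    if len(frames) != len(results):
        raise InputError("results not aligned with frames")
    out = []
    for frame, result, det in zip(frames, results, details):
        base = np.rint(frame.values * (255.0 / GREY_MAX)).astype(np.uint8)
        img = np.stack([base] * 3, axis=-1).astype(np.uint8)
        if det is not None:
            excited = (det.e_potentials > 0) & ~det.shadow_mask
            img[excited] = (255, 40, 40)
            img[det.shadow_mask] = (255, 255, 0)
            if draw_vectors:
                rows, cols = np.nonzero(det.directions >= 0)
                keep = (rows % vector_stride == 0) & (cols % vector_stride == 0)
                for r, c in zip(rows[keep], cols[keep]):
                    ang = np.deg2rad(det.directions[r, c])
                    for step in (1, 2):
                        rr = int(round(r - step * np.sin(ang)))
                        cc = int(round(c + step * np.cos(ang)))
                        if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]:
                            img[rr, cc] = (0, 255, 0)
            if draw_vectors and result.steering_direction is not None:
                row = img.shape[0] - 3
                c0 = img.shape[1] // 2
                span = range(0, 8) if result.steering_direction == "right" else range(-7, 1)
                for dc in span:
                    img[row, np.clip(c0 + dc, 0, img.shape[1] - 1)] = (0, 255, 0)
        if draw_zone:
            _draw_circle(img, zone.center, zone.radius, (60, 120, 255))
        out.append(img)
    if outdir is not None:
        import imageio.v2 as imageio
        from pathlib import Path

        d = Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        for k, img in enumerate(out):
            imageio.imwrite(d / f"overlay_{k:05d}.png", img)
    return out
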