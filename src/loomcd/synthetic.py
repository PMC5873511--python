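"""Seeded synthetic stimulus generator with ground-truth labels.

Produces the canonical test stimuli of looming-detector work: objects on a
direct collision course (radially expanding dark squares), harmless
laterally translating objects, whole-field rigid jitter emulating camera
shake, global luminance flicker, and ground shadows sweeping down across
the road surface below the horizon.  Every generator is deterministic for
a fixed spec + seed and returns frames together with a per-frame truth
table sufficient to score the collision-detection pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .frames_io import GREY_MAX, FrameGrid, frames_from_arrays, write_sequence

__all__ = [
    "StimulusSpec",
    "looming_square",
    "translating_bar",
    "camera_shake",
    "textured_scene",
    "ground_shadow",
    "global_flicker",
    "composite_scene",
    "make_stimulus",
    "write_stimulus",
]

#: Default element lattice (height, width) for synthetic scenes — the
#: native working resolution of the algorithm on dashboard footage.
DEFAULT_SHAPE = (110, 200)
DEFAULT_N_FRAMES = 60
#: High-contrast defaults: dark object on a bright background,
#: Michelson contrast 0.75, well above any configured e-threshold.
DEFAULT_OBJECT = 1.0
DEFAULT_BACKGROUND = 7.0
DEFAULT_NOISE_SD = 0.05
FRAME_RATE = 29.0


@dataclass
class StimulusSpec:
    """Declarative description of a synthetic scene (used by the CLI)."""

    kind: str  # looming | translate | shake | shadow | flicker | composite
    frame_shape: tuple[int, int] = DEFAULT_SHAPE
    n_frames: int = DEFAULT_N_FRAMES
    object_level: float = DEFAULT_OBJECT
    background_level: float = DEFAULT_BACKGROUND
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    params: dict = dc_field(default_factory=dict)


def _background(shape, level, noise_sd, rng) -> np.ndarray:
    """Static textured background: the texture does not move, so it generates
    no e-potentials on its own but gives shake something to displace."""
    bg = level + rng.normal(0.0, noise_sd, size=shape)
    return np.clip(bg, 0.0, GREY_MAX)


def _draw_rect(frame: np.ndarray, x0, x1, y0, y1, level: float) -> np.ndarray:
    """Paint a sub-element-accurate rectangle; edge elements get partial
    coverage so continuous growth/translation changes every frame."""
    h, w = frame.shape
    cols = np.arange(w)
    rows = np.arange(h)
    cov_x = np.clip(np.minimum(x1, cols + 1) - np.maximum(x0, cols), 0.0, 1.0)
    cov_y = np.clip(np.minimum(y1, rows + 1) - np.maximum(y0, rows), 0.0, 1.0)
    cov = np.outer(cov_y, cov_x)
    return frame * (1.0 - cov) + level * cov


def _side_schedule(start: float, end: float, n: int, growth: str) -> np.ndarray:
    t = np.arange(n, dtype=float)
    if growth == "linear":
        return np.linspace(start, end, n)
    if growth == "exponential":
        return np.geomspace(start, end, n)
    if growth == "collision":
        # inverse time-to-contact: the angular-size law of an object
        # approaching at constant speed
        return start * end * (n - 1) / (end * (n - 1) - (end - start) * t)
    raise ConfigError(f"unknown growth mode {growth!r}")


def looming_square(
    frame_shape: tuple[int, int] = DEFAULT_SHAPE,
    n_frames: int = DEFAULT_N_FRAMES,
    start_side: float = 3.0,
    end_side: float = 90.0,
    growth: str = "collision",
    object_level: float = DEFAULT_OBJECT,
    background_level: float = DEFAULT_BACKGROUND,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    center: tuple[float, float] | None = None,
) -> tuple[list[FrameGrid], pd.DataFrame]:
    """Dark square on a collision course: centred, growing radially.

    Default growth follows the inverse time-to-contact law, so expansion
    accelerates toward the end of the sequence as for an object approaching
    at constant speed.
    """
    h, w = frame_shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    sides = _side_schedule(start_side, end_side, n_frames, growth)
    if (
        cx - end_side / 2 < 0
        or cx + end_side / 2 > w
        or cy - end_side / 2 < 0
        or cy + end_side / 2 > h
    ):
        raise ConfigError("looming square grows beyond the frame bounds")
    rng = np.random.default_rng(seed)
    bg = _background(frame_shape, background_level, noise_sd, rng)
    frames, rows = [], []
    for k, side in enumerate(sides):
        half = side / 2.0
        frames.append(
            _draw_rect(bg.copy(), cx - half, cx + half, cy - half, cy + half, object_level)
        )
        rows.append(
            {
                "frame_index": k,
                "on_collision_course": True,
                "side": side,
                "object_area": side * side,
            }
        )
    return frames_from_arrays(frames, FRAME_RATE), pd.DataFrame(rows)


def translating_bar(
    frame_shape: tuple[int, int] = DEFAULT_SHAPE,
    n_frames: int = DEFAULT_N_FRAMES,
    bar_height: float = 40.0,
    bar_width: float = 10.0,
    speed: float = 2.5,
    direction: str = "right",
    object_level: float = DEFAULT_OBJECT,
    background_level: float = DEFAULT_BACKGROUND,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[list[FrameGrid], pd.DataFrame]:
    """Harmless crossing object: a fixed-size bar translating at constant
    velocity through the frame (no retinal expansion, hence no collision)."""
    h, w = frame_shape
    rng = np.random.default_rng(seed)
    bg = _background(frame_shape, background_level, noise_sd, rng)
    cy = (h - 1) / 2.0
    cx = (w - 1) / 2.0
    frames, rows = [], []
    for k in range(n_frames):
        d = speed * k
        if direction == "right":
            x0, y0 = -bar_width + d, cy - bar_height / 2
            bw, bh = bar_width, bar_height
        elif direction == "left":
            x0, y0 = w - d, cy - bar_height / 2
            bw, bh = bar_width, bar_height
        elif direction == "down":
            x0, y0 = cx - bar_height / 2, -bar_width + d
            bw, bh = bar_height, bar_width
        elif direction == "up":
            x0, y0 = cx - bar_height / 2, h - d
            bw, bh = bar_height, bar_width
        else:
            raise ConfigError(f"unknown direction {direction!r}")
        frames.append(_draw_rect(bg.copy(), x0, x0 + bw, y0, y0 + bh, object_level))
        rows.append(
            {
                "frame_index": k,
                "on_collision_course": False,
                "direction": direction,
                "offset": d,
            }
        )
    return frames_from_arrays(frames, FRAME_RATE), pd.DataFrame(rows)


def textured_scene(
    frame_shape: tuple[int, int] = DEFAULT_SHAPE,
    n_frames: int = 20,
    texture: str = "blocks",
    low: float = 1.0,
    high: float = 8.0,
    block_size: int = 8,
    cell: int = 14,
    seed: int = 0,
) -> tuple[list[FrameGrid], pd.DataFrame]:
    """Static random texture, identical on every frame — the base scene for
    camera-shake experiments (a still scene seen by a shaky camera).

    ``texture="blocks"`` scatters solid high-contrast square patches on a
    mid-grey ground: under rigid shifts their edges produce compact motion
    patches that survive the cluster filter and yield local motion vectors.
    ``texture="noise"`` is dense per-element noise: shifts excite almost
    every element, which drives the overstimulation rule instead.
    """
    rng = np.random.default_rng(seed)
    if texture == "noise":
        tex = rng.uniform(low, high, size=frame_shape)
    elif texture == "blocks":
        h, w = frame_shape
        tex = np.full(frame_shape, (low + high) / 2.0)
        for gy in range(0, h, cell):
            for gx in range(0, w, cell):
                oy = int(rng.integers(0, max(cell - block_size, 1)))
                ox = int(rng.integers(0, max(cell - block_size, 1)))
                level = low if rng.random() < 0.5 else high
                tex[gy + oy : gy + oy + block_size, gx + ox : gx + ox + block_size] = level
    else:
        raise ConfigError(f"unknown texture {texture!r}")
    frames = [tex.copy() for _ in range(n_frames)]
    truth = pd.DataFrame({"frame_index": range(n_frames), "on_collision_course": False})
    return frames_from_arrays(frames, FRAME_RATE), truth


def camera_shake(
    frames: list[FrameGrid],
    amplitude: int = 3,
    seed: int = 0,
) -> tuple[list[FrameGrid], pd.DataFrame]:
    """Rigid whole-field jitter of a few elements: each frame shifted by a
    random integer offset drawn uniformly from [-amplitude, amplitude] per
    axis."""
    rng = np.random.default_rng(seed)
    shifts = rng.integers(-amplitude, amplitude + 1, size=(len(frames), 2)) if amplitude else np.zeros((len(frames), 2), dtype=int)
    out, rows = [], []
    for f, (dx, dy) in zip(frames, shifts):
        out.append(np.roll(f.values, shift=(int(dy), int(dx)), axis=(0, 1)))
        rows.append({"frame_index": f.frame_index, "shift_x": int(dx), "shift_y": int(dy)})
    return frames_from_arrays(out, frames[0].frame_rate), pd.DataFrame(rows)


def global_flicker(
    frame_shape: tuple[int, int] = DEFAULT_SHAPE,
    n_frames: int = 20,
    low: float = 2.0,
    high: float = 8.0,
    seed: int = 0,
) -> tuple[list[FrameGrid], pd.DataFrame]:
    """Whole-field luminance jumps with no spatial structure: every element
    changes identically, driving the overstimulation rule without producing
    directional motion."""
    rng = np.random.default_rng(seed)
    levels = rng.uniform(low, high, size=n_frames)
    frames = [np.full(frame_shape, lv) for lv in levels]
    truth = pd.DataFrame({"frame_index": range(n_frames), "level": levels})
    return frames_from_arrays(frames, FRAME_RATE), truth


def ground_shadow(
    frame_shape: tuple[int, int] = DEFAULT_SHAPE,
    n_frames: int = DEFAULT_N_FRAMES,
    horizon_row: float | None = None,
    stripe_height: float = 12.0,
    spawn_interval: int = 9,
    speed: float = 3.0,
    shadow_level: float = 1.5,
    contrast_ramp: float = 0.75,
    background_level: float = DEFAULT_BACKGROUND,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 3,
    counter_motion: bool = True,
) -> tuple[list[FrameGrid], pd.DataFrame]:
    """Ground shadows sweeping down the road surface.

    Dark stripes spanning the road (the middle half of the frame) appear at
    a horizon line just below the frame center and translate rapidly
    towards the lower frame border, emulating tree or bridge shadows the
    vehicle drives across.  Successive stripes darken geometrically (stripe
    *i* reaches a fraction ``1 - contrast_ramp**(i+1)`` of full contrast) —
    the car gliding ever deeper into a shaded stretch — so the strongest
    shadows arrive only once the motion network has a history.  With
    *counter_motion*, vertical stripes drift outward through the side
    panels flanking the road (which lie outside the danger zone), giving
    the scene the lateral scenery flow of forward travel.
    """
    h, w = frame_shape
    if horizon_row is None:
        horizon_row = h / 2.0 + 1.0
    rng = np.random.default_rng(seed)
    bg = _background(frame_shape, background_level, noise_sd, rng)
    frames, rows = [], []
    n_stripes = n_frames // spawn_interval + 1
    # the road (and hence the shadows) occupies the middle half of the
    # frame; the flanking panels carry laterally drifting scenery
    road_x0, road_x1 = w / 4.0, 3.0 * w / 4.0
    for k in range(n_frames):
        frame = bg.copy()
        if counter_motion:
            # scenery optic flow of forward travel: vertical stripes drift
            # outward in the side panels (which lie outside the danger zone)
            spacing, width = 21.0, 6.0
            for panel, sign in (((0.0, road_x0 - 4.0), -1), ((road_x1 + 4.0, float(w)), +1)):
                span = panel[1] - panel[0] + spacing
                for j in range(int(span / spacing) + 1):
                    x = panel[0] + (j * spacing + sign * speed * k) % span - spacing
                    frame = _draw_rect(
                        frame,
                        max(x, panel[0]),
                        min(x + width, panel[1]),
                        0.0,
                        float(h),
                        shadow_level,
                    )
        active = 0
        for i in range(n_stripes):
            y0 = horizon_row + speed * (k - i * spawn_interval)
            if y0 + stripe_height <= horizon_row or y0 >= h:
                continue
            y0c = max(y0, horizon_row)
            # successive shadows darken geometrically towards full contrast:
            # the car glides ever deeper into the shaded stretch of road
            depth = 1.0 - contrast_ramp ** (i + 1) if contrast_ramp else 1.0
            level = background_level - (background_level - shadow_level) * depth
            frame = _draw_rect(frame, road_x0, road_x1, y0c, y0 + stripe_height, level)
            active += 1
        frames.append(frame)
        rows.append(
            {
                "frame_index": k,
                "on_collision_course": False,
                "horizon_row": horizon_row,
                "n_active_stripes": active,
            }
        )
    return frames_from_arrays(frames, FRAME_RATE), pd.DataFrame(rows)


def composite_scene(
    frame_shape: tuple[int, int] = DEFAULT_SHAPE,
    n_frames: int = DEFAULT_N_FRAMES,
    seed: int = 0,
) -> tuple[list[FrameGrid], pd.DataFrame]:
    """Looming square plus ground-shadow stripes in one scene."""
    end_side = 0.75 * min(frame_shape)
    loom, truth = looming_square(frame_shape, n_frames, end_side=end_side, seed=seed)
    shad, _ = ground_shadow(frame_shape, n_frames, seed=seed + 1, counter_motion=True)
    out = [np.minimum(f_l.values, f_s.values) for f_l, f_s in zip(loom, shad)]
    return frames_from_arrays(out, FRAME_RATE), truth


_KINDS = {
    "looming": looming_square,
    "translate": translating_bar,
    "shadow": ground_shadow,
    "flicker": global_flicker,
    "composite": composite_scene,
}


def make_stimulus(spec: StimulusSpec) -> tuple[list[FrameGrid], pd.DataFrame]:
    """Instantiate a stimulus from a declarative spec."""
    kind = spec.kind
    if kind == "shake":
        base, _ = textured_scene(
            spec.frame_shape,
            spec.params.get("n_frames", spec.n_frames),
            seed=spec.seed,
        )
        return camera_shake(
            base, amplitude=spec.params.get("amplitude", 2), seed=spec.seed + 1
        )
    if kind not in _KINDS:
        raise ConfigError(f"unknown stimulus kind {kind!r}")
    fn = _KINDS[kind]
    kwargs = dict(frame_shape=spec.frame_shape, n_frames=spec.n_frames, seed=spec.seed)
    if kind == "looming" and spec.frame_shape != DEFAULT_SHAPE and "end_side" not in spec.params:
        kwargs["end_side"] = 0.75 * min(spec.frame_shape)
    if kind in ("looming", "translate"):
        kwargs.update(
            object_level=spec.object_level,
            background_level=spec.background_level,
            noise_sd=spec.noise_sd,
        )
    kwargs.update(spec.params)
    return fn(**kwargs)


def write_stimulus(
    frames: list[FrameGrid], truth: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write the frames as numbered PNGs plus a truth.csv sidecar."""
    out = Path(outdir)
    write_sequence(frames, out)
    truth_path = out / "truth.csv"
    truth.to_csv(truth_path, index=False)
    return truth_path
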