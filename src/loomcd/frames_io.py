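"""Frame loading and the grey-value convention.

The collision-detection network operates on low-resolution grey frames whose
element values live in ``[0, 9.9]`` (a convention inherited from the
multi-agent environment the algorithm was first prototyped in).  This module
converts image sequences or video files into that convention, and derives the
film-level contrast and the default e-potential threshold from it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
from skimage.transform import resize

from .errors import InputError

__all__ = [
    "GREY_MAX",
    "FrameGrid",
    "ContrastModel",
    "load_sequence",
    "frames_from_arrays",
    "write_sequence",
    "image_contrast",
    "threshold_from_contrast",
]

#: Upper bound of the grey-value range used throughout the network.
GREY_MAX = 9.9

# ITU-R BT.601 luma weights, the conventional grey conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_IMAGE_EXT = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
_VIDEO_EXT = {".avi", ".mp4", ".mov", ".mkv", ".webm"}


@dataclass
class FrameGrid:
    """One grey frame on the element lattice.

    Attributes
    ----------
    values : ndarray, shape (height, width)
        Grey level per element, in ``[0, GREY_MAX]``.
    frame_index : int
        Ordinal position in the sequence.
    frame_rate : float
        Frames per second of the source film.
    """

    values: np.ndarray
    frame_index: int = 0
    frame_rate: float = 29.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("frame values must be a 2-D array")
        if self.values.size and (self.values.min() < 0 or self.values.max() > GREY_MAX):
            raise InputError(
                f"grey values outside [0, {GREY_MAX}]: "
                f"range [{self.values.min():.3g}, {self.values.max():.3g}]"
            )

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]


@dataclass
class ContrastModel:
    """Michelson contrast of a representative frame and the derived threshold.

    ``contrast = (a - b) / (a + b)`` for the highest (*a*) and lowest (*b*)
    grey values; the e-potential threshold follows the empirical line
    ``0.71 * contrast + 0.378`` unless overridden per run.
    """

    a: float
    b: float
    contrast: float = field(init=False)
    e_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.contrast = image_contrast_from_extremes(self.a, self.b)
        self.e_threshold = threshold_from_contrast(self.contrast)


def image_contrast_from_extremes(a: float, b: float) -> float:
    if a < b:
        raise InputError(f"highest grey value {a} below lowest {b}")
    total = a + b
    if total == 0:
        return 0.0
    return (a - b) / total


def image_contrast(frame: FrameGrid | np.ndarray) -> float:
    """Michelson contrast ``(a - b)/(a + b)`` of one frame; 0 for a black frame."""
    values = frame.values if isinstance(frame, FrameGrid) else np.asarray(frame, float)
    if values.size == 0:
        raise InputError("cannot compute contrast of an empty frame")
    return image_contrast_from_extremes(float(values.max()), float(values.min()))


def threshold_from_contrast(contrast: float) -> float:
    """Default e-potential threshold as an empirical linear function of contrast.

    An explicitly configured per-run threshold takes precedence over this
    convenience default (low-contrast films behave better with hand-picked
    values).
    """
    if not 0.0 <= contrast <= 1.0:
        raise InputError(f"contrast {contrast} outside [0, 1]")
    return contrast * 0.71 + 0.378


def _to_grey(img: np.ndarray) -> np.ndarray:
    """Collapse channels and map the native range linearly onto [0, GREY_MAX]."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    arr = arr.astype(float)
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        native_max = float(np.iinfo(np.asarray(img).dtype).max)
    else:
        native_max = 1.0
        arr = np.clip(arr, 0.0, 1.0)
    return arr * (GREY_MAX / native_max)


def _resize_to_width(arr: np.ndarray, target_width: int) -> np.ndarray:
    h, w = arr.shape
    if w == target_width:
        return arr
    target_height = int(round(h * target_width / w))
    out = resize(
        arr,
        (target_height, target_width),
        anti_aliasing=True,
        preserve_range=True,
        mode="reflect",
    )
    return np.clip(out, 0.0, GREY_MAX)


def load_sequence(
    source: str | os.PathLike,
    target_width: int | None = None,
    frame_rate: float = 29.0,
) -> list[FrameGrid]:
    """Load a numbered image sequence (directory) or a video container.

    Frames are converted to single-channel grey, optionally rescaled to
    *target_width* preserving aspect ratio, and mapped linearly onto
    ``[0, GREY_MAX]``.  Frame order follows the lexicographic file order for
    directories and the container order for videos.
    """
    if target_width is not None and target_width < 32:
        raise InputError(f"target_width {target_width} below minimum of 32")
    path = Path(source)
    raw: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXT)
        if not files:
            raise InputError(f"no image frames found in {path}")
        for f in files:
            raw.append(imageio.imread(f))
    elif path.is_file():
        if path.suffix.lower() in _VIDEO_EXT:
            try:
                reader = imageio.get_reader(path)
                meta = reader.get_meta_data()
                frame_rate = float(meta.get("fps", frame_rate))
                raw = [np.asarray(im) for im in reader]
            except Exception as exc:  # pragma: no cover - backend dependent
                raise InputError(f"cannot read video {path}: {exc}") from exc
        else:
            raw = [imageio.imread(path)]
    else:
        raise InputError(f"input source {path} does not exist")
    if not raw:
        raise InputError(f"input source {path} contains zero frames")

    frames = []
    for k, img in enumerate(raw):
        grey = _to_grey(img)
        if target_width is not None:
            grey = _resize_to_width(grey, target_width)
        frames.append(FrameGrid(grey, frame_index=k, frame_rate=frame_rate))
    shapes = {f.values.shape for f in frames}
    if len(shapes) > 1:
        raise InputError(f"frames have inconsistent shapes: {sorted(shapes)}")
    return frames


def frames_from_arrays(
    arrays: list[np.ndarray] | np.ndarray, frame_rate: float = 29.0
) -> list[FrameGrid]:
    """Wrap in-memory grey arrays (already in [0, GREY_MAX]) as FrameGrids."""
    return [FrameGrid(a, frame_index=k, frame_rate=frame_rate) for k, a in enumerate(arrays)]


def write_sequence(frames: list[FrameGrid], outdir: str | os.PathLike) -> list[Path]:
    """Write frames as 8-bit PNGs (grey values quantized from [0, GREY_MAX])."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, f in enumerate(frames):
        img = np.rint(f.values * (255.0 / GREY_MAX)).astype(np.uint8)
        p = out / f"frame_{k:05d}.png"
        imageio.imwrite(p, img)
        paths.append(p)
    return paths
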