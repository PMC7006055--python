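"""Render synthetic marker videos for exercising the template tracker.

Frames are grayscale uint8: dark field, bright circular markers with a one
pixel linear edge falloff (so sub-pixel position is encoded in the rendered
intensities), and a horizontal calibration bar of known pixel length in
frame 0 standing in for the 10 mm radiographic calibration marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..trace import MotionTrace
from .truth import SyntheticTruth


@dataclass
class VideoGeometry:
    """Frame size and drawing parameters for a rendered marker video."""

    height_px: int = 120
    width_px: int = 160
    marker_radius_px: float = 4.0
    calibration_bar_px: int = 100
    calibration_bar_mm: float = 10.0
    bar_origin: tuple[int, int] = (10, 4)  # (x, y) of the bar's left end
    background_level: int = 20
    marker_level: int = 255


def render_marker_video(
    truth: SyntheticTruth,
    geometry: VideoGeometry | None = None,
) -> np.ndarray:
    """Render a ``(n_frames, H, W)`` uint8 video from truth marker positions.

    Every frame contains one bright anti-aliased disk per marker at the truth
    position; frame 0 additionally carries the calibration bar. Raises
    ``ValueError`` if any marker (plus its radius) leaves the frame bounds.
    """
    if truth.marker_positions is None or not truth.marker_positions:
        raise ValueError("truth carries no per-frame marker positions")
    geom = geometry or VideoGeometry()
    labels = list(truth.marker_positions)
    n_frames = np.asarray(truth.marker_positions[labels[0]]).shape[0]
    h, w, r = geom.height_px, geom.width_px, geom.marker_radius_px

    for label in labels:
        pos = np.asarray(truth.marker_positions[label], dtype=float)
        if pos.shape != (n_frames, 2):
            raise ValueError(f"marker {label!r} has inconsistent frame count")
        if (
            np.any(pos[:, 0] < r)
            or np.any(pos[:, 0] > w - 1 - r)
            or np.any(pos[:, 1] < r)
            or np.any(pos[:, 1] > h - 1 - r)
        ):
            raise ValueError(f"marker {label!r} leaves the frame bounds")

    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.full((n_frames, h, w), geom.background_level, dtype=np.uint8)
    span = geom.marker_level - geom.background_level
    for f in range(n_frames):
        img = np.zeros((h, w), dtype=float)
        for label in labels:
            x, y = truth.marker_positions[label][f]
            dist = np.hypot(xx - x, yy - y)
            # 1 px linear falloff at the rim encodes sub-pixel position
            img = np.maximum(img, np.clip(r + 0.5 - dist, 0.0, 1.0))
        frames[f] = (geom.background_level + span * img).astype(np.uint8)

    bx, by = geom.bar_origin
    if bx + geom.calibration_bar_px > w:
        raise ValueError("calibration bar does not fit in the frame")
    frames[0, by : by + 2, bx : bx + geom.calibration_bar_px] = geom.marker_level
    return frames


def jaw_marker_truth(
    trace: MotionTrace,
    truth: SyntheticTruth,
    mm_per_pixel: float = 0.1,
    upper_xy: tuple[float, float] = (80.0, 30.0),
) -> SyntheticTruth:
    """Attach fluoroscopy marker positions for a jaw gape trace.

    The upper-jaw marker is static; the lower-jaw marker hangs straight below
    it at the per-frame gape distance converted to pixels, mirroring the
    upper/lower jaw marker pair placed in the first fluoroscopy frame.
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    n = len(trace)
    ux, uy = upper_xy
    upper = np.tile([ux, uy], (n, 1)).astype(float)
    lower = np.column_stack(
        [np.full(n, ux), uy + trace.values / mm_per_pixel]
    )
    truth.marker_positions = {"upper_jaw": upper, "lower_jaw": lower}
    return truth


def write_frames_png(frames: np.ndarray, directory) -> list[str]:
    """Write frames as numbered PNGs (``frame_0000.png``, ...)."""
    import os

    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        path = os.path.join(str(directory), f"frame_{i:04d}.png")
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def read_frames_png(directory) -> np.ndarray:
    """Read a numbered-PNG directory back into a ``(n, H, W)`` array."""
    import glob
    import os

    import imageio.v3 as iio

    paths = sorted(glob.glob(os.path.join(str(directory), "frame_*.png")))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files under {directory}")
    return np.stack([iio.imread(p) for p in paths])
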