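"""Marker tracking and calibrated kinematic trace extraction.

Converts video frames plus first-frame manual marker placements into
calibrated time series: jaw gape in mm for fluoroscopy, signed lateral
glottal coordinates in px for endoscopy.

Conventions: image origin top-left, x rightward, y downward, 0-based frames.

The tracker is normalized cross-correlation template matching: a
``(2h+1) x (2h+1)`` patch captured around each marker in frame 0 is searched
within a fixed radius of the previous frame's position, with parabolic
sub-pixel refinement of the correlation peak. The template is never updated,
so there is no drift; a confidence floor turns a bad match into an explicit
tracking-lost error rather than a silent jump.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .trace import MotionTrace

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class CalibrationScale:
    """Pixel-to-mm conversion from a traced calibration bar."""

    mm_per_pixel: float
    source_length_px: float

    def __post_init__(self) -> None:
        if not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive")


def calibrate_scale(bar_length_px: float, bar_length_mm: float = 10.0) -> CalibrationScale:
    """Scale from the traced length in px of a bar of known mm length."""
    if not bar_length_px > 0:
        raise ValueError("bar_length_px must be positive")
    if not bar_length_mm > 0:
        raise ValueError("bar_length_mm must be positive")
    return CalibrationScale(
        mm_per_pixel=bar_length_mm / bar_length_px, source_length_px=bar_length_px
    )


@dataclass
class MarkerTrack:
    """Per-frame (x, y) positions and match confidences for one marker."""

    label: str
    positions: np.ndarray  # (n_frames, 2) float
    confidence: np.ndarray  # (n_frames,) in [0, 1]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_frames, 2)")
        if self.confidence.shape != (self.positions.shape[0],):
            raise ValueError("one confidence per frame required")

    def __len__(self) -> int:
        return self.positions.shape[0]


class TrackingLostError(RuntimeError):
    """Raised when the best template match drops below the confidence floor."""

    def __init__(self, label: str, frame_index: int, score: float):
        self.label = label
        self.frame_index = frame_index
        self.score = score
        super().__init__(
            f"lost marker {label!r} at frame {frame_index} (match score {score:.3f})"
        )


def _as_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        return frame @ _LUMA
    return frame


def _parabolic_offset(m1: float, m0: float, p1: float) -> float:
    denom = m1 - 2.0 * m0 + p1
    if denom >= 0 or abs(denom) < 1e-12:
        return 0.0
    off = 0.5 * (m1 - p1) / denom
    return float(np.clip(off, -0.5, 0.5))


def track_markers(
    frames,
    initial_positions,
    template_half_width_px: int = 5,
    search_radius_px: int = 8,
    confidence_floor: float = 0.5,
    labels: list[str] | None = None,
) -> list[MarkerTrack]:
    """Track each marker through all frames by NCC template matching.

    Parameters
    ----------
    frames
        Sequence of >= 2 grayscale (or RGB) frames of equal shape.
    initial_positions
        One (x, y) per marker, inside frame 0 with the full template patch.
    template_half_width_px
        Patch half-width ``h``; the template is ``(2h+1)`` square.
    search_radius_px
        Maximum allowed inter-frame displacement.
    confidence_floor
        Minimum acceptable NCC score; below it a
        :class:`TrackingLostError` names the offending frame.
    """
    gray = [_as_gray(f) for f in frames]
    if len(gray) < 2:
        raise ValueError("need at least 2 frames")
    h_img, w_img = gray[0].shape
    th = int(template_half_width_px)
    if th < 1:
        raise ValueError("template_half_width_px must be >= 1")
    sr = int(search_radius_px)
    if sr < 1:
        raise ValueError("search_radius_px must be >= 1")

    initial_positions = [tuple(map(float, p)) for p in initial_positions]
    if labels is None:
        labels = [f"marker_{i}" for i in range(len(initial_positions))]
    if len(labels) != len(initial_positions):
        raise ValueError("one label per initial position required")

    tracks = []
    for label, (x0, y0) in zip(labels, initial_positions):
        xi, yi = int(round(x0)), int(round(y0))
        if not (th <= xi < w_img - th and th <= yi < h_img - th):
            raise ValueError(
                f"initial position for {label!r} too close to the frame border "
                "for the template patch"
            )
        template = gray[0][yi - th : yi + th + 1, xi - th : xi + th + 1]
        if np.ptp(template) == 0:
            raise ValueError(f"featureless template for {label!r} in frame 0")
        # the patch is cut on the integer grid but represents the marker at
        # its stated sub-pixel position; carry that capture offset forward
        cap_dx, cap_dy = x0 - xi, y0 - yi

        positions = np.empty((len(gray), 2), dtype=float)
        confidence = np.empty(len(gray), dtype=float)
        positions[0] = (x0, y0)
        confidence[0] = 1.0
        px, py = x0, y0
        for f in range(1, len(gray)):
            cx, cy = int(round(px)), int(round(py))
            x_lo = max(cx - sr - th, 0)
            x_hi = min(cx + sr + th + 1, w_img)
            y_lo = max(cy - sr - th, 0)
            y_hi = min(cy + sr + th + 1, h_img)
            window = gray[f][y_lo:y_hi, x_lo:x_hi]
            if window.shape[0] < 2 * th + 1 or window.shape[1] < 2 * th + 1:
                raise TrackingLostError(label, f, float("-inf"))
            corr = match_template(window, template)
            iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
            score = float(corr[iy, ix])
            if score < confidence_floor:
                raise TrackingLostError(label, f, score)
            dx = dy = 0.0
            if 0 < ix < corr.shape[1] - 1:
                dx = _parabolic_offset(corr[iy, ix - 1], score, corr[iy, ix + 1])
            if 0 < iy < corr.shape[0] - 1:
                dy = _parabolic_offset(corr[iy - 1, ix], score, corr[iy + 1, ix])
            px = x_lo + ix + th + dx + cap_dx
            py = y_lo + iy + th + dy + cap_dy
            positions[f] = (px, py)
            confidence[f] = min(max(score, 0.0), 1.0)
        tracks.append(MarkerTrack(label=label, positions=positions, confidence=confidence))
    return tracks


def jaw_gape_trace(
    upper: MarkerTrack, lower: MarkerTrack, scale: CalibrationScale, fps: float
) -> MotionTrace:
    """Per-frame Euclidean marker separation converted to mm."""
    if len(upper) != len(lower):
        raise ValueError("upper and lower tracks must have equal length")
    d = np.hypot(
        upper.positions[:, 0] - lower.positions[:, 0],
        upper.positions[:, 1] - lower.positions[:, 1],
    )
    return MotionTrace(values=d * scale.mm_per_pixel, fps=fps, units="mm")


def adjust_glottal_points(left, right, commissure):
    """Equalize the two glottal-edge points' distances from the commissure.

    The nearer point is moved outward along the ray from the commissure
    through it to the distance of the farther point; the farther point is the
    reference and is unchanged. Idempotent; raises on a point coincident with
    the commissure.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    commissure = np.asarray(commissure, dtype=float)
    vl = left - commissure
    vr = right - commissure
    dl = float(np.hypot(*vl))
    dr = float(np.hypot(*vr))
    if dl == 0.0 or dr == 0.0:
        raise ValueError("glottal point coincides with the dorsal commissure")
    target = max(dl, dr)
    left_out = commissure + vl * (target / dl)
    right_out = commissure + vr * (target / dr)
    return left_out, right_out


def glottal_lateral_traces(
    left: MarkerTrack,
    right: MarkerTrack,
    commissure: MarkerTrack,
    fps: float,
) -> tuple[MotionTrace, MotionTrace, MotionTrace]:
    """Signed lateral coordinates about the fixed frame-0 glottal axis.

    The glottal axis is the bisector of the angle left-commissure-right in
    frame 0, anchored at the frame-0 commissure. Each point's lateral
    coordinate is its signed perpendicular distance from that fixed axis,
    negative toward the frame-0 left point and positive toward the right one.
    Also returns the glottal width trace |L - R| per frame.
    """
    if not (len(left) == len(right) == len(commissure)):
        raise ValueError("tracks must have equal length")
    c0 = commissure.positions[0]
    ul = left.positions[0] - c0
    ur = right.positions[0] - c0
    nl, nr = np.hypot(*ul), np.hypot(*ur)
    if nl == 0 or nr == 0:
        raise ValueError("glottal point coincides with the commissure in frame 0")
    axis = ul / nl + ur / nr
    norm = np.hypot(*axis)
    if norm < 1e-12:
        raise ValueError("degenerate geometry: glottal points are anti-parallel")
    axis /= norm
    normal = np.array([-axis[1], axis[0]])
    if np.dot(right.positions[0] - c0, normal) < 0:
        normal = -normal  # right side positive by convention

    lat_l = (left.positions - c0) @ normal
    lat_r = (right.positions - c0) @ normal
    width = np.hypot(
        left.positions[:, 0] - right.positions[:, 0],
        left.positions[:, 1] - right.positions[:, 1],
    )
    return (
        MotionTrace(values=lat_l, fps=fps, units="px"),
        MotionTrace(values=lat_r, fps=fps, units="px"),
        MotionTrace(values=width, fps=fps, units="px"),
    )
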