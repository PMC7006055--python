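"""Synthetic glottal (vocal fold / arytenoid) lateral-motion traces.

Emulates the oscillatory abduction/adduction of the left and right glottal
edges during spontaneous breathing as seen through a transoral endoscope.
Lateral coordinates use the shared image convention of the tracking module:
negative = left of the glottal midline axis, positive = right of it.

Normal motion is anti-phase in the signed coordinate (both sides move
*outward* together on inspiration: left more negative, right more positive),
so per-frame velocities of the two traces correlate at exactly -1.
Paradoxical motion moves both edges in the same image direction, giving a
velocity correlation of exactly +1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..trace import MotionTrace
from ._rng import make_rng
from .truth import SyntheticTruth

_EDGE_EPS = 1e-9


@dataclass
class GlottalTraceSpec:
    """Parameters of a synthetic 10 s breathing clip.

    Attributes
    ----------
    respiratory_rate_per_min
        Breathing cycles per minute (sedated adult mice: ~140-170).
    left_amplitude_px, right_amplitude_px
        Lateral excursion of each glottal edge over a cycle, in pixels.
        Unequal amplitudes model asymmetric motion (MMRR < 1).
    baseline_halfwidth_px
        Half of the glottal width at maximal adduction (expiration).
    paradoxical
        If True, both edges move in the same image direction.
    noise_sd_px, duration_s, fps, seed
        As in the jaw generator.
    """

    respiratory_rate_per_min: float = 150.0
    left_amplitude_px: float = 10.0
    right_amplitude_px: float = 10.0
    baseline_halfwidth_px: float = 4.0
    paradoxical: bool = False
    noise_sd_px: float = 0.0
    duration_s: float = 10.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.respiratory_rate_per_min > 0:
            raise ValueError("respiratory_rate_per_min must be positive")
        if self.left_amplitude_px < 0 or self.right_amplitude_px < 0:
            raise ValueError("amplitudes must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        f = self.respiratory_rate_per_min / 60.0
        if self.fps < 2.0 * f:
            raise ValueError("fps undersamples the respiratory cycle")
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")


def gen_glottal_traces(
    spec: GlottalTraceSpec,
) -> tuple[MotionTrace, MotionTrace, SyntheticTruth]:
    """Generate left/right lateral traces plus ground truth.

    Truth events: ``abduction_peak`` (glottis maximally open) at
    (k + 1/2)/f and ``adduction_trough`` (maximally closed) at k/f, for the
    complete cycles inside the clip.
    """
    f = spec.respiratory_rate_per_min / 60.0
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    # d(t) rises 0 -> 1 over the abduction half-cycle; cycle starts closed.
    d = 0.5 * (1.0 - np.cos(2 * np.pi * f * t))

    if spec.paradoxical:
        left = -spec.baseline_halfwidth_px + spec.left_amplitude_px * d
        right = spec.baseline_halfwidth_px + spec.right_amplitude_px * d
    else:
        left = -(spec.baseline_halfwidth_px + spec.left_amplitude_px * d)
        right = spec.baseline_halfwidth_px + spec.right_amplitude_px * d

    if spec.noise_sd_px > 0:
        rng = make_rng(spec.seed)
        left = left + rng.normal(0.0, spec.noise_sd_px, size=n)
        right = right + rng.normal(0.0, spec.noise_sd_px, size=n)

    n_cycles = int(math.floor(spec.duration_s * f + _EDGE_EPS))
    open_times = (np.arange(n_cycles) + 0.5) / f
    close_times = np.arange(n_cycles + 1) / f
    close_times = close_times[close_times < spec.duration_s - _EDGE_EPS]

    truth = SyntheticTruth(
        event_times={
            "abduction_peak": open_times,
            "adduction_trough": close_times,
        },
        true_parameters={
            "respiratory_rate_per_min": spec.respiratory_rate_per_min,
            "left_amplitude_px": spec.left_amplitude_px,
            "right_amplitude_px": spec.right_amplitude_px,
            "baseline_halfwidth_px": spec.baseline_halfwidth_px,
            "paradoxical": spec.paradoxical,
            "noise_sd_px": spec.noise_sd_px,
            "duration_s": spec.duration_s,
            "fps": spec.fps,
            "seed": spec.seed,
            "n_cycles": n_cycles,
        },
    )
    left_trace = MotionTrace(values=left, fps=spec.fps, units="px")
    right_trace = MotionTrace(values=right, fps=spec.fps, units="px")
    return left_trace, right_trace, truth


def glottal_marker_positions(
    left: MotionTrace,
    right: MotionTrace,
    commissure_xy: tuple[float, float] = (80.0, 30.0),
    axial_offset_px: float = 40.0,
) -> dict[str, np.ndarray]:
    """Per-frame 2-D positions for the three endoscopy markers.

    The dorsal commissure is static; the left/right vocal-process markers sit
    ``axial_offset_px`` ventral (image-down) of it, displaced laterally by the
    signed trace values. Suitable for rendering marker videos and for the
    angle metrics.
    """
    n = len(left)
    cx, cy = commissure_xy
    comm = np.tile([cx, cy], (n, 1)).astype(float)
    lpos = np.column_stack([cx + left.values, np.full(n, cy + axial_offset_px)])
    rpos = np.column_stack([cx + right.values, np.full(n, cy + axial_offset_px)])
    return {"left_glottal": lpos, "right_glottal": rpos, "dorsal_commissure": comm}
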