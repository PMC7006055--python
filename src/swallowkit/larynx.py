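"""Laryngeal motion metrics from glottal lateral traces.

Five metrics describe vocal fold (VF) motion over a 10 s spontaneous
breathing clip:

* **MMRR** (mean motion range ratio) — left/right amplitude symmetry per
  respiratory cycle, averaged; reported as min/max so 1.0 = symmetric.
* **OCCR** (open-close cycle ratio) — right cycle count / left cycle count.
* **Mcorr** (motion correlation coefficient) — Pearson correlation of the
  per-frame motion directions (first differences) of the two sides on the
  shared image axis: -1 = normal anti-phase motion, +1 = paradoxical
  same-direction motion, ~0 = little or no motion.
* **VF angle** — the angle left-commissure-right, max and min per cycle,
  averaged (degrees).
* **Respiratory rate** — glottal width cycles per minute.

Cycle segmentation for the cycle-based metrics comes from the glottal
*width* trace (the two-sided consensus); per-side extrema counts feed only
OCCR, which is precisely the statistic that may differ between sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._peaks import default_prominence, detect_alternating_extrema
from .tracking import MarkerTrack
from .trace import MotionTrace


@dataclass
class SideCycle:
    """One respiratory cycle on one side."""

    open_time: float  # max abduction (s)
    close_time: float  # max adduction (s)
    amplitude: float  # lateral excursion within the cycle (px)


@dataclass
class WidthCycle:
    """One consensus cycle segmented from the glottal width trace."""

    start_time: float
    peak_time: float
    end_time: float
    amp_left: float
    amp_right: float


@dataclass
class RespiratoryCycles:
    left: list[SideCycle]
    right: list[SideCycle]
    width_cycles: list[WidthCycle]


@dataclass
class LaryngealMetrics:
    mmrr: float
    occr: float
    mcorr: float
    vf_angle_max: float
    vf_angle_min: float
    vf_angle_mean: float
    respiratory_rate: float  # cycles/min


@dataclass
class LARResponse:
    """Laryngeal adductor reflex annotation (presence scored manually)."""

    present: bool
    start_frame: int | None = None
    end_frame: int | None = None


def _side_cycles(excursion: np.ndarray, fps: float, prom: float) -> list[SideCycle]:
    """Cycles from one side's outward-excursion signal (opens = maxima)."""
    max_idx, min_idx = detect_alternating_extrema(excursion, prom)
    cycles = []
    for o in max_idx:
        later_min = min_idx[min_idx > o]
        close = int(later_min[0]) if later_min.size else None
        prev_min = min_idx[min_idx < o]
        floor_vals = [excursion[i] for i in ([prev_min[-1]] if prev_min.size else [])]
        if close is not None:
            floor_vals.append(excursion[close])
        amp = excursion[o] - min(floor_vals) if floor_vals else 0.0
        cycles.append(
            SideCycle(
                open_time=o / fps,
                close_time=(close / fps) if close is not None else float("nan"),
                amplitude=float(amp),
            )
        )
    return cycles


def detect_respiratory_cycles(
    left: MotionTrace,
    right: MotionTrace,
    width: MotionTrace,
    min_prominence_px: float | None = None,
) -> RespiratoryCycles:
    """Segment respiratory cycles from lateral and width traces.

    Per-side extrema are found on each side's outward excursion (the signed
    lateral coordinate flipped for the left side so 'open' is a maximum on
    both sides). Consensus cycles come from the width trace: one cycle per
    width maximum, bounded by the surrounding width minima, carrying each
    side's lateral range within the bounds. Flat traces yield zero cycles.
    """
    if not (len(left) == len(right) == len(width)):
        raise ValueError("traces must have equal length")
    if len(width) < 3:
        raise ValueError("need at least 3 samples")
    fps = width.fps

    exc_l = -left.values
    exc_r = right.values
    prom_l = min_prominence_px if min_prominence_px is not None else default_prominence(exc_l)
    prom_r = min_prominence_px if min_prominence_px is not None else default_prominence(exc_r)
    left_cycles = _side_cycles(exc_l, fps, prom_l) if prom_l > 0 else []
    right_cycles = _side_cycles(exc_r, fps, prom_r) if prom_r > 0 else []

    prom_w = (
        min_prominence_px if min_prominence_px is not None else default_prominence(width.values)
    )
    width_cycles: list[WidthCycle] = []
    if prom_w > 0:
        w_max, w_min = detect_alternating_extrema(width.values, prom_w)
        for peak in w_max:
            before = w_min[w_min < peak]
            after = w_min[w_min > peak]
            start = int(before[-1]) if before.size else 0
            end = int(after[0]) if after.size else len(width) - 1
            seg = slice(start, end + 1)
            width_cycles.append(
                WidthCycle(
                    start_time=start / fps,
                    peak_time=peak / fps,
                    end_time=end / fps,
                    amp_left=float(np.ptp(left.values[seg])),
                    amp_right=float(np.ptp(right.values[seg])),
                )
            )
    return RespiratoryCycles(left=left_cycles, right=right_cycles, width_cycles=width_cycles)


def _angles_deg(
    left: MarkerTrack, right: MarkerTrack, commissure: MarkerTrack
) -> np.ndarray:
    vl = left.positions - commissure.positions
    vr = right.positions - commissure.positions
    dot = np.sum(vl * vr, axis=1)
    norms = np.hypot(vl[:, 0], vl[:, 1]) * np.hypot(vr[:, 0], vr[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dot / norms, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def compute_laryngeal_metrics(
    cycles: RespiratoryCycles,
    left: MotionTrace,
    right: MotionTrace,
    tracks: tuple[MarkerTrack, MarkerTrack, MarkerTrack] | None = None,
    clip_seconds: float = 10.0,
    smooth_window: int = 3,
) -> LaryngealMetrics:
    """Compute the five laryngeal metrics (NaN where undefined).

    ``tracks`` is the (left, right, commissure) marker-track triple needed
    for the VF angle; without it the angle metrics are missing. MMRR uses
    min/max amplitude ordering (symmetric, <= 1); OCCR uses the fixed
    right/left count order. Mcorr correlates per-frame first differences
    after a light moving-average pre-smoothing (``smooth_window`` frames,
    default 3; 1 disables it) that suppresses frame-to-frame tracking
    jitter without touching the breathing-rate signal — ideal anti-phase
    motion still gives exactly -1 and paradoxical motion exactly +1.
    """
    per_cycle_ratio = []
    for wc in cycles.width_cycles:
        hi = max(wc.amp_left, wc.amp_right)
        if hi > 0:
            per_cycle_ratio.append(min(wc.amp_left, wc.amp_right) / hi)
    mmrr = float(np.mean(per_cycle_ratio)) if per_cycle_ratio else float("nan")

    occr = (
        len(cycles.right) / len(cycles.left) if len(cycles.left) else float("nan")
    )

    if smooth_window > 1:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        lv = np.convolve(left.values, kernel, mode="valid")
        rv = np.convolve(right.values, kernel, mode="valid")
    else:
        lv, rv = left.values, right.values
    dl = np.diff(lv)
    dr = np.diff(rv)
    if dl.size >= 2 and np.std(dl) > 0 and np.std(dr) > 0:
        mcorr = float(np.corrcoef(dl, dr)[0, 1])
    else:
        mcorr = float("nan")  # ~0 motion: correlation undefined

    vf_max = vf_min = vf_mean = float("nan")
    if tracks is not None and cycles.width_cycles:
        ang = _angles_deg(*tracks)
        fps = left.fps
        maxima, minima, means = [], [], []
        for wc in cycles.width_cycles:
            seg = ang[int(round(wc.start_time * fps)) : int(round(wc.end_time * fps)) + 1]
            seg = seg[np.isfinite(seg)]
            if seg.size:
                maxima.append(seg.max())
                minima.append(seg.min())
                means.append(0.5 * (seg.max() + seg.min()))
        if maxima:
            vf_max = float(np.mean(maxima))
            vf_min = float(np.mean(minima))
            vf_mean = float(np.mean(means))

    respiratory_rate = len(cycles.width_cycles) * 60.0 / clip_seconds
    return LaryngealMetrics(
        mmrr=mmrr,
        occr=float(occr),
        mcorr=mcorr,
        vf_angle_max=vf_max,
        vf_angle_min=vf_min,
        vf_angle_mean=vf_mean,
        respiratory_rate=respiratory_rate,
    )


def lar_duration(resp: LARResponse, fps: float) -> float:
    """LAR duration in ms from annotated start/end frames.

    An absent response yields a missing value (NaN); a present response with
    ``end_frame < start_frame`` is an argument error. A normal reflex is
    brief (well under 1 s of glottic closure).
    """
    if not resp.present:
        return float("nan")
    if resp.start_frame is None or resp.end_frame is None:
        raise ValueError("present LAR response requires start and end frames")
    if resp.end_frame < resp.start_frame:
        raise ValueError("end_frame must be >= start_frame")
    if not fps > 0:
        raise ValueError("fps must be positive")
    return (resp.end_frame - resp.start_frame) / fps * 1000.0
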