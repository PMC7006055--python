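"""Jaw open/close cycle detection and drinking/eating metric computation.

The fluoroscopic workflow: a raw drinking or eating recording is spliced
into clips that *start on a swallow event* (five context frames are added to
each end for frame-by-frame review but excluded from analysis), jaw gape
extrema are detected and optionally hand-edited, and the metric set is
computed over the clip's analysis window — 2 s for drinking, 20 s for
eating.

Counting conventions (the upstream software leaves these unstated, so they
are fixed here): a cycle is timestamped by its closing minimum; per-second
counting uses half-open sub-windows [0,1), [1,2), ...; the lick-swallow
ratio counts cycles in the half-open interval (s_i, s_{i+1}] between
successive swallows; phase velocities are per-phase mean slopes
(amplitude / phase duration). Metrics that are undefined for a clip (e.g.
no swallow pair for an inter-swallow interval) are reported as missing
values (NaN), never as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from ._peaks import default_prominence, detect_alternating_extrema
from .trace import MotionTrace

_EPS = 1e-9


@dataclass(frozen=True)
class CycleEvents:
    """Timestamps (s) of gape maxima (jaw open) and minima (jaw closed)."""

    open_times: np.ndarray
    close_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "open_times", np.sort(np.asarray(self.open_times, float)))
        object.__setattr__(self, "close_times", np.sort(np.asarray(self.close_times, float)))
        for name in ("open_times", "close_times"):
            t = getattr(self, name)
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    # -- manual review/edit hooks (mirroring the interactive interface) -----
    def add_open(self, t: float) -> "CycleEvents":
        return replace(self, open_times=np.append(self.open_times, t))

    def add_close(self, t: float) -> "CycleEvents":
        return replace(self, close_times=np.append(self.close_times, t))

    def remove_open(self, t: float, tol: float = 1e-6) -> "CycleEvents":
        keep = np.abs(self.open_times - t) > tol
        if keep.all():
            raise ValueError(f"no open event at t={t}")
        return replace(self, open_times=self.open_times[keep])

    def remove_close(self, t: float, tol: float = 1e-6) -> "CycleEvents":
        keep = np.abs(self.close_times - t) > tol
        if keep.all():
            raise ValueError(f"no close event at t={t}")
        return replace(self, close_times=self.close_times[keep])

    def alternates(self) -> bool:
        """True when opens and closes strictly alternate in time."""
        merged = sorted(
            [(t, +1) for t in self.open_times] + [(t, -1) for t in self.close_times]
        )
        return all(a[1] != b[1] for a, b in zip(merged, merged[1:]))


@dataclass
class SwallowAnnotation:
    """Manually annotated swallow: rest frame, esophagus entry, clip anchor.

    ``rest_frame`` is the frame immediately preceding visible bolus transfer
    out of the vallecula (the swallow trigger point); the bolus tail enters
    the esophagus at ``esophagus_entry_frame``. ``swallow_frame`` anchors
    clip splicing and swallow-rate counting (by default the rest frame).
    """

    rest_frame: int
    esophagus_entry_frame: int
    swallow_frame: int | None = None

    def __post_init__(self) -> None:
        if self.swallow_frame is None:
            self.swallow_frame = self.rest_frame
        if self.esophagus_entry_frame <= self.rest_frame:
            raise ValueError("esophagus_entry_frame must follow rest_frame")


@dataclass
class DrinkingMetrics:
    """The drinking metric set for one 2 s clip (NaN = undefined)."""

    lick_rate: float  # jaw cycles per second (#/s)
    inter_lick_interval: float  # ms
    swallow_rate: float  # #/s
    inter_swallow_interval: float  # ms
    lick_swallow_ratio: float  # cycles per swallow pair
    pharyngeal_transit_time: float  # ms
    jaw_opening_velocity: float  # mm/s
    jaw_closing_velocity: float  # mm/s


@dataclass
class EatingMetrics:
    """The eating metric set for one 20 s clip (NaN = undefined)."""

    mastication_rate: float  # #/s during rotary chewing
    swallow_rate: float  # #/s
    inter_swallow_interval: float  # s


def splice_clip(
    trace: MotionTrace,
    swallow_frame: int,
    clip_seconds: float = 2.0,
    context_frames: int = 5,
) -> tuple[MotionTrace, tuple[int, int]]:
    """Cut an analysis clip starting at a swallow event.

    Returns the clip (context frames included, clamped at the recording
    boundaries) and the half-open analysis window ``(start, stop)`` in
    clip-local frame indices; metrics are computed only inside the window,
    which spans ``clip_seconds * fps`` frames beginning at the swallow.
    """
    n = len(trace)
    if not 0 <= swallow_frame < n:
        raise ValueError(f"swallow_frame {swallow_frame} outside trace of {n} frames")
    win_frames = int(round(clip_seconds * trace.fps))
    clip_start = max(0, swallow_frame - context_frames)
    clip_stop = min(n, swallow_frame + win_frames + context_frames)
    clip = MotionTrace(
        values=trace.values[clip_start:clip_stop], fps=trace.fps, units=trace.units
    )
    w0 = swallow_frame - clip_start
    w1 = min(w0 + win_frames, len(clip))
    return clip, (w0, w1)


def detect_jaw_cycles(
    trace: MotionTrace, min_prominence_mm: float | None = None
) -> CycleEvents:
    """Detect alternating open (max) / close (min) jaw events.

    The prominence threshold defaults to 20% of the clip's gape range. A
    constant trace yields an empty event set (not an error). Event times are
    frame-quantized (multiples of 1/fps).
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples")
    prom = (
        min_prominence_mm
        if min_prominence_mm is not None
        else default_prominence(trace.values)
    )
    if prom <= 0:  # constant trace
        return CycleEvents(open_times=np.array([]), close_times=np.array([]))
    max_idx, min_idx = detect_alternating_extrema(trace.values, prom)
    return CycleEvents(open_times=max_idx / trace.fps, close_times=min_idx / trace.fps)


def _per_second_counts(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    n_windows = int(round(t1 - t0))
    counts = np.empty(max(n_windows, 0))
    for k in range(n_windows):
        lo, hi = t0 + k, t0 + k + 1
        counts[k] = np.count_nonzero((times >= lo - _EPS) & (times < hi - _EPS))
    return counts


def _phase_velocities(
    events: CycleEvents, trace: MotionTrace, t0: float, t1: float
) -> tuple[float, float]:
    """Mean per-phase slopes (opening = close->open, closing = open->close)."""
    merged = sorted(
        [(t, "open") for t in events.open_times]
        + [(t, "close") for t in events.close_times]
    )
    def gape_at(t: float) -> float:
        f = int(round(t * trace.fps))
        return trace.values[min(max(f, 0), len(trace) - 1)]

    opening, closing = [], []
    for (ta, ka), (tb, kb) in zip(merged, merged[1:]):
        if not (t0 - _EPS <= tb < t1 - _EPS):  # phase assigned by ending event
            continue
        if tb <= ta:
            continue
        slope = abs(gape_at(tb) - gape_at(ta)) / (tb - ta)
        if ka == "close" and kb == "open":
            opening.append(slope)
        elif ka == "open" and kb == "close":
            closing.append(slope)
    v_open = float(np.mean(opening)) if opening else float("nan")
    v_close = float(np.mean(closing)) if closing else float("nan")
    return v_open, v_close


def compute_drinking_metrics(
    events: CycleEvents,
    swallows: list[SwallowAnnotation],
    trace: MotionTrace,
    window: tuple[int, int],
) -> DrinkingMetrics:
    """All drinking metrics over a clip's analysis window.

    ``window`` is the half-open clip-local frame range from
    :func:`splice_clip`; annotation frames are clip-local as well.
    """
    t0, t1 = window[0] / trace.fps, window[1] / trace.fps
    closes = events.close_times
    in_win = closes[(closes >= t0 - _EPS) & (closes < t1 - _EPS)]

    lick_counts = _per_second_counts(closes, t0, t1)
    lick_rate = float(np.mean(lick_counts)) if lick_counts.size else float("nan")
    ili = float(np.mean(np.diff(in_win)) * 1000.0) if in_win.size >= 2 else float("nan")

    if not swallows:
        warnings.warn(
            "no swallow annotations: swallow-based metrics reported as missing",
            stacklevel=2,
        )
        s_times = np.array([])
    else:
        s_times = np.sort(np.array([s.swallow_frame / trace.fps for s in swallows]))
    s_in = s_times[(s_times >= t0 - _EPS) & (s_times < t1 - _EPS)]

    s_counts = _per_second_counts(s_times, t0, t1)
    swallow_rate = float(np.mean(s_counts)) if s_counts.size else float("nan")
    isi = float(np.mean(np.diff(s_in)) * 1000.0) if s_in.size >= 2 else float("nan")

    if s_in.size >= 2:
        per_pair = [
            np.count_nonzero((closes > lo + _EPS) & (closes <= hi + _EPS))
            for lo, hi in zip(s_in, s_in[1:])
        ]
        ratio = float(np.mean(per_pair))
    else:
        ratio = float("nan")

    if swallows:
        ptt = float(
            np.mean(
                [
                    (s.esophagus_entry_frame - s.rest_frame) / trace.fps * 1000.0
                    for s in swallows
                ]
            )
        )
    else:
        ptt = float("nan")

    v_open, v_close = _phase_velocities(events, trace, t0, t1)
    return DrinkingMetrics(
        lick_rate=lick_rate,
        inter_lick_interval=ili,
        swallow_rate=swallow_rate,
        inter_swallow_interval=isi,
        lick_swallow_ratio=ratio,
        pharyngeal_transit_time=ptt,
        jaw_opening_velocity=v_open,
        jaw_closing_velocity=v_close,
    )


def compute_eating_metrics(
    events: CycleEvents,
    swallows: list[SwallowAnnotation],
    rotary_intervals: list[tuple[int, int]],
    trace: MotionTrace,
    window: tuple[int, int],
) -> EatingMetrics:
    """Eating metrics over a 20 s window.

    ``rotary_intervals`` are manually annotated ~1 s episodes of rotary
    mastication, as half-open clip-local frame ranges; the study protocol
    uses exactly three (fewer triggers a warning and uses what is given).
    """
    t0, t1 = window[0] / trace.fps, window[1] / trace.fps
    if len(rotary_intervals) != 3:
        warnings.warn(
            f"expected 3 rotary mastication intervals, got {len(rotary_intervals)}",
            stacklevel=2,
        )
    rates = []
    closes = events.close_times
    for start_f, stop_f in rotary_intervals:
        lo, hi = start_f / trace.fps, stop_f / trace.fps
        if lo < t0 - _EPS or hi > t1 + _EPS:
            raise ValueError("rotary interval outside the analysis window")
        count = np.count_nonzero((closes >= lo - _EPS) & (closes < hi - _EPS))
        rates.append(count / (hi - lo))
    mastication_rate = float(np.mean(rates)) if rates else float("nan")

    s_times = np.sort(np.array([s.swallow_frame / trace.fps for s in swallows]))
    s_in = s_times[(s_times >= t0 - _EPS) & (s_times < t1 - _EPS)]
    s_counts = _per_second_counts(s_times, t0, t1)
    swallow_rate = float(np.mean(s_counts)) if s_counts.size else float("nan")
    isi = float(np.mean(np.diff(s_in))) if s_in.size >= 2 else float("nan")
    return EatingMetrics(
        mastication_rate=mastication_rate,
        swallow_rate=swallow_rate,
        inter_swallow_interval=isi,
    )


#: column names for exported per-mouse records
METRIC_COLUMNS = {
    "lick_rate": "Lick rate (#/s)",
    "inter_lick_interval": "Inter-lick interval (ms)",
    "swallow_rate": "Swallow rate (#/s)",
    "inter_swallow_interval": "Inter-swallow interval (ms)",
    "lick_swallow_ratio": "Lick-swallow ratio",
    "pharyngeal_transit_time": "Pharyngeal transit time (ms)",
    "jaw_closing_velocity": "Jaw closing velocity (mm/s)",
    "jaw_opening_velocity": "Jaw opening velocity (mm/s)",
    "mastication_rate": "Mastication rate (#/s)",
    "eating_swallow_rate": "Eating swallow rate (#/s)",
    "eating_inter_swallow_interval": "Eating inter-swallow interval (s)",
}


@dataclass
class MetricsRecord:
    """One mouse's clip-averaged drinking and eating metrics."""

    drinking: DrinkingMetrics
    eating: EatingMetrics | None = None

    def to_series(self, mouse_id: str | None = None) -> pd.Series:
        data = {
            METRIC_COLUMNS[f.name]: getattr(self.drinking, f.name)
            for f in fields(DrinkingMetrics)
        }
        if self.eating is not None:
            data[METRIC_COLUMNS["mastication_rate"]] = self.eating.mastication_rate
            data[METRIC_COLUMNS["eating_swallow_rate"]] = self.eating.swallow_rate
            data[METRIC_COLUMNS["eating_inter_swallow_interval"]] = (
                self.eating.inter_swallow_interval
            )
        return pd.Series(data, name=mouse_id)


def _nanmean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    good = arr[~np.isnan(arr)]
    return float(np.mean(good)) if good.size else float("nan")


def aggregate_mouse(
    drinking_clips: list[DrinkingMetrics],
    eating_clip: EatingMetrics | None = None,
) -> MetricsRecord:
    """Unweighted per-metric mean across a mouse's clips.

    The study protocol analyzes five 2 s drinking clips and one 20 s eating
    clip per mouse; 1-5 drinking clips are accepted. Missing clip values are
    ignored in the mean; a metric missing in every clip stays missing.
    """
    if not drinking_clips:
        raise ValueError("need at least one drinking clip")
    if len(drinking_clips) > 5:
        warnings.warn("more than 5 drinking clips supplied", stacklevel=2)
    avg = DrinkingMetrics(
        **{
            f.name: _nanmean([getattr(c, f.name) for c in drinking_clips])
            for f in fields(DrinkingMetrics)
        }
    )
    return MetricsRecord(drinking=avg, eating=eating_clip)
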