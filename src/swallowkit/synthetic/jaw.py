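"""Synthetic jaw gape traces emulating fluoroscopic drinking/eating clips.

The waveform is a raised cosine, gape(t) = baseline + (A/2)(1 - cos 2*pi*f*t),
so the jaw is fully closed (gape = baseline) at t = k/f and maximally open at
t = (k + 1/2)/f: every cycle extremum is analytically known and the generator
can emit exact ground truth for the downstream peak detector and metric layer.

Default parameters follow the wild-type drinking condition of the study this
pipeline reproduces: ~8.71 licks/s recorded at 30 fps, with a swallow every
few licks and a pharyngeal transit of a few frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..trace import MotionTrace
from ._rng import make_rng
from .truth import SyntheticTruth

#: tolerance for "a cycle boundary lands exactly on the clip end"
_EDGE_EPS = 1e-9


@dataclass
class JawTraceSpec:
    """Parameters of a synthetic drinking or eating jaw-motion clip.

    Attributes
    ----------
    lick_rate_hz
        Jaw open/close cycles per second (licking ~8-9 Hz, rotary chewing
        ~8 Hz in mice).
    amplitude_mm
        Peak-to-trough gape excursion. The default 0.79 mm makes the mean
        opening-phase velocity 2 * A * f match the reported ~13.7 mm/s.
    baseline_mm
        Minimum gape: the distance between the upper and lower jaw markers
        with the jaw closed (a couple of mm in an adult mouse, which also
        keeps rendered marker disks from overlapping).
    duration_s, fps
        Clip length and frame rate (the study recorded at 30 fps).
    noise_sd_mm
        SD of additive white Gaussian measurement noise.
    swallow_every_n_licks
        If set, a swallow event is placed at every n-th cycle minimum
        (the "rest frame"), starting at t = 0 so a clip can begin on a
        swallow as the splicing convention requires.
    ptt_frames
        Bolus transit length per swallow, in frames; the esophagus-entry
        frame is the rest frame plus this many frames.
    seed
        Integer seed; same (spec, seed) is bit-reproducible.
    """

    lick_rate_hz: float = 8.71
    amplitude_mm: float = 0.79
    baseline_mm: float = 2.0
    duration_s: float = 2.0
    fps: float = 30.0
    noise_sd_mm: float = 0.0
    swallow_every_n_licks: int | None = 4
    ptt_frames: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lick_rate_hz > 0:
            raise ValueError("lick_rate_hz must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.fps < 2.0 * self.lick_rate_hz:
            raise ValueError(
                f"fps {self.fps} undersamples a {self.lick_rate_hz} Hz cycle "
                "(need fps >= 2 * lick_rate_hz)"
            )
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be positive")
        if self.swallow_every_n_licks is not None and self.swallow_every_n_licks < 1:
            raise ValueError("swallow_every_n_licks must be >= 1")
        if self.ptt_frames < 1:
            raise ValueError("ptt_frames must be >= 1")


def gen_jaw_trace(spec: JawTraceSpec) -> tuple[MotionTrace, SyntheticTruth]:
    """Generate a jaw gape trace plus exact ground truth.

    Truth events (times in seconds):

    * ``jaw_open`` — cycle maxima at (k + 1/2)/f for each complete cycle,
    * ``jaw_close`` — cycle minima at k/f (including t = 0), strictly inside
      the clip,
    * ``swallow`` — rest-frame times of the synthetic swallows.

    ``truth.annotations`` carries one swallow-annotation dict per swallow
    with ``rest_frame``, ``esophagus_entry_frame`` and ``swallow_frame``.
    """
    f = spec.lick_rate_hz
    n = int(round(spec.duration_s * spec.fps))
    if n < 3:
        raise ValueError("clip too short: fewer than 3 frames")
    t = np.arange(n) / spec.fps
    gape = spec.baseline_mm + 0.5 * spec.amplitude_mm * (1.0 - np.cos(2 * np.pi * f * t))
    if spec.noise_sd_mm > 0:
        rng = make_rng(spec.seed)
        gape = gape + rng.normal(0.0, spec.noise_sd_mm, size=n)

    n_cycles = int(math.floor(spec.duration_s * f + _EDGE_EPS))
    open_times = (np.arange(n_cycles) + 0.5) / f
    close_times = np.arange(n_cycles + 1) / f
    close_times = close_times[close_times < spec.duration_s - _EDGE_EPS]

    annotations: list[dict] = []
    swallow_times: list[float] = []
    if spec.swallow_every_n_licks is not None:
        step = spec.swallow_every_n_licks
        for k in range(0, close_times.size, step):
            rest_time = close_times[k]
            rest_frame = int(round(rest_time * spec.fps))
            entry_frame = rest_frame + spec.ptt_frames
            if entry_frame >= n:
                continue
            swallow_times.append(rest_time)
            annotations.append(
                {
                    "rest_frame": rest_frame,
                    "esophagus_entry_frame": entry_frame,
                    "swallow_frame": rest_frame,
                }
            )

    truth = SyntheticTruth(
        event_times={
            "jaw_open": open_times,
            "jaw_close": close_times,
            "swallow": np.asarray(swallow_times),
        },
        true_parameters={
            "lick_rate_hz": f,
            "amplitude_mm": spec.amplitude_mm,
            "baseline_mm": spec.baseline_mm,
            "duration_s": spec.duration_s,
            "fps": spec.fps,
            "noise_sd_mm": spec.noise_sd_mm,
            "swallow_every_n_licks": spec.swallow_every_n_licks,
            "ptt_frames": spec.ptt_frames,
            "seed": spec.seed,
            "n_cycles": n_cycles,
        },
        annotations=annotations,
    )
    return MotionTrace(values=gape, fps=spec.fps, units="mm"), truth
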