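"""Simulated study cohorts run through the full analysis pipeline.

Each ``simulate_*_cohort`` function draws per-mouse parameters around the
published genotype means (``swallowkit.reference``), generates the
corresponding raw synthetic data, runs the *actual* analysis path
(peak detection, metric computation, pixel pipeline, binning) on it, and
returns tidy per-mouse tables plus a separate genotype map — genotype
labels are kept apart from the measurements and merged only at the
statistics stage, mirroring the blinded workflow.

Mouse-to-mouse spread is the published SEM scaled back to a per-animal SD
(SEM * sqrt(n) at the study group sizes).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .. import reference
from ..behavior import bin_events, summarize_behavior
from ..histology import inflammation_ratio
from ..jaw import (
    SwallowAnnotation,
    aggregate_mouse,
    compute_drinking_metrics,
    compute_eating_metrics,
    detect_jaw_cycles,
)
from ..larynx import compute_laryngeal_metrics, detect_respiratory_cycles
from ..tracking import MarkerTrack, glottal_lateral_traces
from ._rng import make_rng
from .glottal import GlottalTraceSpec, gen_glottal_traces, glottal_marker_positions
from .histology import HistologyImageSpec, gen_histology_image
from .homecage import BehaviorLogSpec, gen_homecage_log
from .jaw import JawTraceSpec, gen_jaw_trace

_GENOTYPES = ("wt", "lgdel")


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _mouse_ids(n_wt: int, n_lgdel: int) -> tuple[list[str], pd.Series]:
    ids = [f"wt_{i:02d}" for i in range(n_wt)] + [f"ld_{i:02d}" for i in range(n_lgdel)]
    genotypes = pd.Series(
        ["wt"] * n_wt + ["lgdel"] * n_lgdel, index=ids, name="genotype"
    )
    return ids, genotypes


# --------------------------------------------------------------------------
# VFSS (drinking + eating)
# --------------------------------------------------------------------------

def simulate_vfss_mouse(
    genotype: str,
    seed: int,
    n_drinking_clips: int = 5,
    fps: float = 30.0,
    noise_fraction: float = 0.05,
):
    """One mouse's VFSS session: five 2 s drinking clips + one 20 s eating clip.

    Per-clip lick rate jitters mildly around the mouse's own rate; the
    pharyngeal transit per swallow is an integer number of frames whose mean
    matches the genotype's transit time. Returns the clip-averaged
    :class:`~swallowkit.jaw.MetricsRecord`.
    """
    rng = make_rng(seed)
    means = reference.VFSS_GROUP_MEANS[genotype]
    sems = reference.VFSS_GROUP_SEMS[genotype]
    n_group = 11  # study group size

    lick_rate = rng.normal(means["lick_rate"], sems["lick_rate"] * math.sqrt(n_group))
    lick_rate = float(np.clip(lick_rate, 5.0, 12.0))
    amplitude = means["jaw_opening_velocity"] / (2.0 * lick_rate)
    ptt_frames_mean = means["pharyngeal_transit_time"] * fps / 1000.0

    drinking = []
    for _ in range(n_drinking_clips):
        clip_rate = float(np.clip(rng.normal(lick_rate, 0.1), 5.0, 12.0))
        lo = math.floor(ptt_frames_mean)
        ptt_frames = lo + int(rng.random() < (ptt_frames_mean - lo))
        spec = JawTraceSpec(
            lick_rate_hz=clip_rate,
            amplitude_mm=amplitude,
            duration_s=2.0,
            fps=fps,
            noise_sd_mm=noise_fraction * amplitude,
            swallow_every_n_licks=4,
            ptt_frames=max(ptt_frames, 1),
            seed=_child_seed(rng),
        )
        trace, truth = gen_jaw_trace(spec)
        events = detect_jaw_cycles(trace)
        swallows = [SwallowAnnotation(**a) for a in truth.annotations]
        window = (0, int(round(2.0 * fps)))
        drinking.append(compute_drinking_metrics(events, swallows, trace, window))

    chew_rate = float(
        np.clip(rng.normal(means["mastication_rate"], 0.3), 5.0, 12.0)
    )
    eat_swallow_rate = float(
        np.clip(
            rng.normal(
                means["eating_swallow_rate"],
                sems["eating_swallow_rate"] * math.sqrt(n_group),
            ),
            0.1,
            1.0,
        )
    )
    eat_spec = JawTraceSpec(
        lick_rate_hz=chew_rate,
        amplitude_mm=amplitude * 1.5,
        duration_s=20.0,
        fps=fps,
        noise_sd_mm=noise_fraction * amplitude,
        swallow_every_n_licks=max(int(round(chew_rate / eat_swallow_rate)), 1),
        ptt_frames=3,
        seed=_child_seed(rng),
    )
    eat_trace, eat_truth = gen_jaw_trace(eat_spec)
    eat_events = detect_jaw_cycles(eat_trace)
    eat_swallows = [SwallowAnnotation(**a) for a in eat_truth.annotations]
    window = (0, int(round(20.0 * fps)))
    rotary = [(60, 90), (270, 300), (480, 510)]  # three annotated 1 s episodes
    eating = compute_eating_metrics(eat_events, eat_swallows, rotary, eat_trace, window)
    return aggregate_mouse(drinking, eating)


def simulate_vfss_cohort(
    seed: int, n_wt: int = 11, n_lgdel: int = 11
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-mouse VFSS metric table for a two-genotype cohort."""
    rng = make_rng(seed)
    ids, genotypes = _mouse_ids(n_wt, n_lgdel)
    rows = {}
    for mouse_id in ids:
        genotype = genotypes[mouse_id]
        record = simulate_vfss_mouse(genotype, _child_seed(rng))
        rows[mouse_id] = record.to_series()
    return pd.DataFrame(rows).T, genotypes


# --------------------------------------------------------------------------
# Laryngeal motion
# --------------------------------------------------------------------------

def simulate_laryngeal_mouse(genotype: str, seed: int, fps: float = 30.0):
    """One 10 s breathing clip run through the glottal geometry path."""
    rng = make_rng(seed)
    means = reference.LARYNGEAL_GROUP_MEANS[genotype]
    n_group = 11
    sems = reference.LARYNGEAL_GROUP_SEMS[genotype]
    rate = float(
        np.clip(
            rng.normal(
                means["respiratory_rate"],
                sems["respiratory_rate"] * math.sqrt(n_group),
            ),
            60.0,
            300.0,
        )
    )
    amp_ratio = float(
        np.clip(rng.normal(means["mmrr"], sems["mmrr"] * math.sqrt(n_group)), 0.3, 1.0)
    )
    left_amp = 10.0
    # half the angle sets the lateral offset at a fixed axial distance
    spec = GlottalTraceSpec(
        respiratory_rate_per_min=rate,
        left_amplitude_px=left_amp,
        right_amplitude_px=left_amp * amp_ratio,
        baseline_halfwidth_px=4.0,
        noise_sd_px=0.3,
        duration_s=10.0,
        fps=fps,
        seed=_child_seed(rng),
    )
    lt, rt, truth = gen_glottal_traces(spec)
    pos = glottal_marker_positions(lt, rt)
    tracks = tuple(
        MarkerTrack(label=k, positions=v, confidence=np.ones(len(lt)))
        for k, v in (
            ("left_glottal", pos["left_glottal"]),
            ("right_glottal", pos["right_glottal"]),
            ("dorsal_commissure", pos["dorsal_commissure"]),
        )
    )
    lat_l, lat_r, width = glottal_lateral_traces(tracks[0], tracks[1], tracks[2], fps)
    cycles = detect_respiratory_cycles(lat_l, lat_r, width)
    return compute_laryngeal_metrics(cycles, lat_l, lat_r, tracks=tracks)


def simulate_laryngeal_cohort(
    seed: int, n_wt: int = 11, n_lgdel: int = 11
) -> tuple[pd.DataFrame, pd.Series]:
    rng = make_rng(seed)
    ids, genotypes = _mouse_ids(n_wt, n_lgdel)
    rows = {}
    for mouse_id in ids:
        metrics = simulate_laryngeal_mouse(genotypes[mouse_id], _child_seed(rng))
        rows[mouse_id] = pd.Series(
            {
                "MMRR": metrics.mmrr,
                "OCCR": metrics.occr,
                "Mcorr": metrics.mcorr,
                "VF angle (degrees)": metrics.vf_angle_mean,
                "Respiratory rate (#/min)": metrics.respiratory_rate,
            }
        )
    return pd.DataFrame(rows).T, genotypes


# --------------------------------------------------------------------------
# Histology
# --------------------------------------------------------------------------

def simulate_histology_mouse(genotype: str, seed: int, n_images: int = 5):
    """Five synthetic lung images through the inflammation pipeline.

    Returns (pipeline mean ratio, true mean painted fraction).
    """
    rng = make_rng(seed)
    mean_pct = reference.INFLAMMATION_PERCENT[genotype]
    sd_pct = reference.INFLAMMATION_SEM_PERCENT[genotype] * math.sqrt(11)
    mouse_pct = float(np.clip(rng.normal(mean_pct, sd_pct), 0.05, 40.0))
    images, truths = [], []
    for _ in range(n_images):
        frac = float(np.clip(mouse_pct / 100.0 * rng.uniform(0.8, 1.2), 5e-4, 0.45))
        img, truth = gen_histology_image(
            HistologyImageSpec(pool_area_fraction=frac, seed=_child_seed(rng))
        )
        images.append(img)
        truths.append(truth.true_inflamed_fraction)
    result = inflammation_ratio(images)
    return result.mean_ratio, float(np.mean(truths))


def simulate_histology_cohort(
    seed: int, n_wt: int = 11, n_lgdel: int = 11
) -> tuple[pd.DataFrame, pd.Series]:
    rng = make_rng(seed)
    ids, genotypes = _mouse_ids(n_wt, n_lgdel)
    rows = {}
    for mouse_id in ids:
        measured, true = simulate_histology_mouse(genotypes[mouse_id], _child_seed(rng))
        rows[mouse_id] = pd.Series(
            {"inflammation_ratio": measured, "true_fraction": true}
        )
    return pd.DataFrame(rows).T, genotypes


# --------------------------------------------------------------------------
# Home-cage behavior
# --------------------------------------------------------------------------

def simulate_behavior_mouse(genotype: str, seed: int, total_hours: float = 72.0):
    """A 72 h log binned and summarized into the reported units."""
    rng = make_rng(seed)
    hourly = reference.BEHAVIOR_HOURLY_MEANS[genotype]
    rates = {
        cls: max(float(rng.normal(hourly[cls]["frequency_per_h"], 0.08 * hourly[cls]["frequency_per_h"])), 0.01)
        for cls in ("drinking", "eating", "grooming")
    }
    durations = {
        cls: reference.mean_event_duration_s(genotype, cls)
        for cls in ("drinking", "eating", "grooming")
    }
    spec = BehaviorLogSpec(
        rates_per_hour=rates,
        mean_event_duration_s=durations,
        total_hours=total_hours,
        seed=_child_seed(rng),
    )
    log, _ = gen_homecage_log(spec)
    binned = bin_events(log, bin_hours=24.0, total_hours=total_hours)
    return summarize_behavior(binned, classes=("drinking", "eating", "grooming"))


def simulate_behavior_cohort(
    seed: int, n_wt: int = 5, n_lgdel: int = 5
) -> tuple[pd.DataFrame, pd.Series]:
    rng = make_rng(seed)
    ids, genotypes = _mouse_ids(n_wt, n_lgdel)
    rows = {}
    for mouse_id in ids:
        summary = simulate_behavior_mouse(genotypes[mouse_id], _child_seed(rng))
        row = {}
        for cls in summary.per_mouse.index:
            row[f"{cls} frequency (events/hour)"] = summary.per_mouse.loc[
                cls, "frequency_per_hour"
            ]
            row[f"{cls} duration (minutes/24 h)"] = summary.per_mouse.loc[
                cls, "duration_min"
            ]
        rows[mouse_id] = pd.Series(row)
    return pd.DataFrame(rows).T, genotypes
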