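"""Plain-text readers and writers for the pipeline's file formats.

All coordinates use the image convention stated by the tracking module:
origin top-left, x rightward, y downward, 0-based frame indices.

Formats:
    * marker tracks: CSV (frame, label, x, y, confidence)
    * marker seeds: JSON {label: [x, y]} for first-frame placements
    * swallow annotations: CSV (mouse_id, clip_id, rest_frame,
      esophagus_entry_frame, swallow_frame)
    * behavior logs: CSV (class, start_s, duration_s)
    * traces: see :meth:`swallowkit.trace.MotionTrace.to_csv`
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .jaw import SwallowAnnotation
from .tracking import MarkerTrack


def write_tracks_csv(tracks: list[MarkerTrack], path) -> None:
    frames = []
    for track in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "frame": np.arange(len(track)),
                    "label": track.label,
                    "x": track.positions[:, 0],
                    "y": track.positions[:, 1],
                    "confidence": track.confidence,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path) -> list[MarkerTrack]:
    df = pd.read_csv(path)
    tracks = []
    for label, sub in df.groupby("label", sort=False):
        sub = sub.sort_values("frame")
        tracks.append(
            MarkerTrack(
                label=str(label),
                positions=sub[["x", "y"]].to_numpy(),
                confidence=sub["confidence"].to_numpy(),
            )
        )
    return tracks


def write_marker_seeds(seeds: dict[str, tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: [float(v[0]), float(v[1])] for k, v in seeds.items()}, fh)


def read_marker_seeds(path) -> dict[str, tuple[float, float]]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}


def write_swallow_annotations(
    annotations: list[SwallowAnnotation], path, mouse_id: str = "", clip_id: str = ""
) -> None:
    pd.DataFrame(
        {
            "mouse_id": mouse_id,
            "clip_id": clip_id,
            "rest_frame": [a.rest_frame for a in annotations],
            "esophagus_entry_frame": [a.esophagus_entry_frame for a in annotations],
            "swallow_frame": [a.swallow_frame for a in annotations],
        }
    ).to_csv(path, index=False)


def read_swallow_annotations(path) -> list[SwallowAnnotation]:
    df = pd.read_csv(path)
    return [
        SwallowAnnotation(
            rest_frame=int(r.rest_frame),
            esophagus_entry_frame=int(r.esophagus_entry_frame),
            swallow_frame=int(r.swallow_frame),
        )
        for r in df.itertuples()
    ]


def write_behavior_log(log: pd.DataFrame, path) -> None:
    log[["class", "start_s", "duration_s"]].to_csv(path, index=False)


def read_behavior_log(path) -> pd.DataFrame:
    return pd.read_csv(path)
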