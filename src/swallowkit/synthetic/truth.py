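"""Ground-truth sidecar emitted by every synthetic generator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class SyntheticTruth:
    """What a generator actually produced, for downstream verification.

    Attributes
    ----------
    event_times
        Per event class (e.g. ``"jaw_open"``, ``"swallow"``), ordered
        timestamps in seconds from the start of the generated recording.
    true_parameters
        Echo of the generating spec plus any derived quantities (e.g. the
        exact painted pool-pixel fraction).
    marker_positions
        Per marker label, an ``(n_frames, 2)`` array of (x, y) pixel
        positions; only video-producing generators fill this.
    masks
        Named boolean pixel masks (image generators only), e.g. the painted
        pool mask and the background mask.
    true_inflamed_fraction
        Painted pool pixels / total pixels (histology generator only).
    annotations
        Manual-annotation records the generator would hand to a human rater
        (e.g. swallow rest/esophagus-entry frames).
    """

    event_times: dict[str, np.ndarray] = field(default_factory=dict)
    true_parameters: dict[str, Any] = field(default_factory=dict)
    marker_positions: dict[str, np.ndarray] | None = None
    masks: dict[str, np.ndarray] | None = None
    true_inflamed_fraction: float | None = None
    annotations: list[dict] | None = None

    def __post_init__(self) -> None:
        self.event_times = {
            k: np.asarray(v, dtype=float) for k, v in self.event_times.items()
        }
        for name, t in self.event_times.items():
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"event times for {name!r} must be ascending")

    def to_json(self, path) -> None:
        """Write a JSON sidecar (masks and marker arrays are summarized)."""
        payload: dict[str, Any] = {
            "event_times": {k: v.tolist() for k, v in self.event_times.items()},
            "true_parameters": _jsonable(self.true_parameters),
        }
        if self.true_inflamed_fraction is not None:
            payload["true_inflamed_fraction"] = self.true_inflamed_fraction
        if self.annotations is not None:
            payload["annotations"] = self.annotations
        if self.marker_positions is not None:
            payload["marker_positions"] = {
                k: np.asarray(v).tolist() for k, v in self.marker_positions.items()
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
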