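"""Scalar kinematic time series sampled at a fixed frame rate.

A :class:`MotionTrace` is the common currency of the pipeline: jaw gape in mm
from fluoroscopy, or a glottal lateral coordinate in px from endoscopy. One
value per video frame, frame 0 at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MotionTrace:
    """A scalar signal sampled once per video frame.

    Parameters
    ----------
    values
        One finite value per frame.
    fps
        Frame rate in frames per second; must be positive.
    units
        Unit tag, e.g. ``"mm"`` for jaw gape or ``"px"`` for glottal
        coordinates.
    """

    values: np.ndarray
    fps: float
    units: str = "mm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fps

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.values.size) / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(self.values.size),
                "time_s": self.times,
                "value": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float | None = None, units: str = "mm") -> "MotionTrace":
        """Read a trace written by :meth:`to_csv`.

        If ``fps`` is omitted it is inferred from the median spacing of the
        ``time_s`` column.
        """
        df = pd.read_csv(path)
        if fps is None:
            dt = np.median(np.diff(df["time_s"].to_numpy()))
            if not dt > 0:
                raise ValueError("cannot infer fps from time column")
            fps = 1.0 / dt
        return cls(values=df["value"].to_numpy(), fps=float(fps), units=units)
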