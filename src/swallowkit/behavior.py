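"""Home-cage behavior log binning and summarization.

A behavior log is the export of an automated cage-monitoring classifier:
one row per event with its class (drinking, eating, grooming, ...), start
time in seconds from recording onset, and duration in seconds. A 72 h
recording is split into three 24 h bins; an event belongs wholly to the bin
containing its *start* time (events are never split). Per-mouse values are
the mean over bins, then converted to the reported units: frequency in
events/hour (per-bin mean / bin hours) and duration in minutes per 24 h
(per-bin seconds / 60).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOG_COLUMNS = ["class", "start_s", "duration_s"]


def events_per_hour(frequency_per_bin: float, bin_hours: float = 24.0) -> float:
    """Convert a per-bin event count to events/hour (exact rational /24)."""
    if bin_hours <= 0:
        raise ValueError("bin_hours must be positive")
    return frequency_per_bin / bin_hours


def minutes_per_bin(duration_s_per_bin: float) -> float:
    """Convert per-bin seconds of behavior to minutes per bin (/60)."""
    return duration_s_per_bin / 60.0


def lint_log(log: pd.DataFrame, total_hours: float | None = None) -> None:
    """Consistency checks on a raw event log.

    Verifies required columns, non-negative durations, chronological order,
    no overlapping events, and (when ``total_hours`` is given) that every
    event starts within the recording. Raises ``ValueError`` on violation.
    """
    for col in LOG_COLUMNS:
        if col not in log.columns:
            raise ValueError(f"log is missing column {col!r}")
    start = log["start_s"].to_numpy(dtype=float)
    dur = log["duration_s"].to_numpy(dtype=float)
    if np.any(dur < 0):
        raise ValueError("negative event duration")
    if np.any(np.diff(start) < 0):
        raise ValueError("log is not sorted by start time")
    if np.any(start < 0):
        raise ValueError("event starts before the recording")
    ends = start + dur
    if start.size > 1 and np.any(start[1:] < ends[:-1] - 1e-9):
        raise ValueError("overlapping events in log")
    if total_hours is not None and np.any(start > total_hours * 3600.0):
        raise ValueError("event starts beyond the recording end")


def bin_events(
    log: pd.DataFrame, bin_hours: float = 24.0, total_hours: float = 72.0
) -> pd.DataFrame:
    """Assign each event to its 24 h bin by start time.

    Returns a copy of the log with an integer ``bin`` column; the number of
    bins is ``total_hours / bin_hours`` and empty bins still exist
    downstream (they contribute zero frequency and duration).
    """
    if bin_hours <= 0 or total_hours <= 0:
        raise ValueError("bin_hours and total_hours must be positive")
    n_bins = int(round(total_hours / bin_hours))
    if abs(n_bins * bin_hours - total_hours) > 1e-9:
        raise ValueError("total_hours must be a whole number of bins")
    start = log["start_s"].to_numpy(dtype=float)
    if np.any(start < 0) or np.any(start > total_hours * 3600.0):
        raise ValueError("event outside the recording period")
    out = log.copy()
    bins = np.minimum((start / (bin_hours * 3600.0)).astype(int), n_bins - 1)
    out["bin"] = bins
    out.attrs["n_bins"] = n_bins
    out.attrs["bin_hours"] = bin_hours
    return out


@dataclass
class BehaviorSummary:
    """Per-bin and per-mouse (bin-averaged, unit-converted) summaries.

    ``per_bin`` has one row per (class, bin) with integer ``frequency``
    (events in that bin) and ``duration_s`` (summed seconds). ``per_mouse``
    has one row per class with the bin means and the converted units.
    """

    per_bin: pd.DataFrame
    per_mouse: pd.DataFrame
    bin_hours: float


def summarize_behavior(binned: pd.DataFrame, classes=None) -> BehaviorSummary:
    """Frequency and duration per class per bin, averaged per mouse.

    ``classes`` fixes the class set (so classes with zero events still get
    rows); by default the classes present in the log are used.
    """
    n_bins = binned.attrs.get("n_bins")
    bin_hours = binned.attrs.get("bin_hours", 24.0)
    if n_bins is None:
        n_bins = int(binned["bin"].max()) + 1 if len(binned) else 1
    if classes is None:
        classes = sorted(binned["class"].unique())

    rows = []
    for cls in classes:
        sub = binned[binned["class"] == cls]
        for b in range(n_bins):
            in_bin = sub[sub["bin"] == b]
            rows.append(
                {
                    "class": cls,
                    "bin": b,
                    "frequency": int(len(in_bin)),
                    "duration_s": float(in_bin["duration_s"].sum()),
                }
            )
    per_bin = pd.DataFrame(rows)

    mouse_rows = []
    for cls in classes:
        sub = per_bin[per_bin["class"] == cls]
        freq = float(sub["frequency"].mean())
        dur = float(sub["duration_s"].mean())
        mouse_rows.append(
            {
                "class": cls,
                "frequency_per_bin": freq,
                "duration_s_per_bin": dur,
                "frequency_per_hour": events_per_hour(freq, bin_hours),
                "duration_min": minutes_per_bin(dur),
            }
        )
    per_mouse = pd.DataFrame(mouse_rows).set_index("class")
    return BehaviorSummary(per_bin=per_bin, per_mouse=per_mouse, bin_hours=bin_hours)
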