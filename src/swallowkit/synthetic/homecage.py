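"""Synthetic home-cage behavior event logs.

Emulates the export of an automated cage-monitoring classifier: a
chronological list of (behavior class, start timestamp, duration) rows over a
72 h recording. Per class, event counts are Poisson with mean
rate * total_hours; starts are uniform over the recording; durations are
exponential around the class mean. Events of one animal may not overlap, so
an event whose drawn start collides with an already-placed one is redrawn
(its start resampled) rather than dropped — per-class counts stay exactly
Poisson while the log remains strictly non-overlapping.

Default rates/durations follow the wild-type home-cage condition
(e.g. drinking ~3.43 events/h of ~1.3 s each).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import reference
from ._rng import make_rng
from .truth import SyntheticTruth


def _default_rates() -> dict[str, float]:
    wt = reference.BEHAVIOR_HOURLY_MEANS["wt"]
    return {cls: wt[cls]["frequency_per_h"] for cls in ("drinking", "eating", "grooming")}


def _default_durations() -> dict[str, float]:
    return {
        cls: reference.mean_event_duration_s("wt", cls)
        for cls in ("drinking", "eating", "grooming")
    }


@dataclass
class BehaviorLogSpec:
    """Parameters of a synthetic behavior log.

    ``rates_per_hour`` maps behavior class to mean event rate (events/h);
    ``mean_event_duration_s`` maps class to mean event length in seconds.
    """

    rates_per_hour: dict[str, float] = field(default_factory=_default_rates)
    mean_event_duration_s: dict[str, float] = field(default_factory=_default_durations)
    total_hours: float = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.total_hours > 0:
            raise ValueError("total_hours must be positive")
        for cls, r in self.rates_per_hour.items():
            if r < 0:
                raise ValueError(f"rate for {cls!r} must be >= 0")
            if r > 0 and self.mean_event_duration_s.get(cls, 0.0) <= 0:
                raise ValueError(f"mean duration for {cls!r} must be positive")

    @property
    def expected_occupancy(self) -> float:
        """Expected fraction of the recording occupied by events."""
        busy = sum(
            r * self.mean_event_duration_s.get(cls, 0.0)
            for cls, r in self.rates_per_hour.items()
        )
        return busy / 3600.0


def gen_homecage_log(spec: BehaviorLogSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a non-overlapping, time-ordered behavior event log.

    Returns a DataFrame with columns ``class``, ``start_s``, ``duration_s``
    sorted by start time, plus truth listing per-class start times.

    Raises ``ValueError`` when the requested rates/durations are so high that
    events cannot avoid overlapping.
    """
    if spec.expected_occupancy > 0.5:
        raise ValueError(
            f"expected occupancy {spec.expected_occupancy:.2f} > 0.5: "
            "events cannot reliably avoid overlap"
        )
    rng = make_rng(spec.seed)
    total_s = spec.total_hours * 3600.0

    # Draw all events first (Poisson counts, exponential durations) ...
    pending: list[tuple[str, float]] = []
    for cls in sorted(spec.rates_per_hour):
        rate = spec.rates_per_hour[cls]
        if rate == 0:
            continue
        n = rng.poisson(rate * spec.total_hours)
        durations = rng.exponential(spec.mean_event_duration_s[cls], size=n)
        pending.extend((cls, float(d)) for d in durations)

    # ... then place them longest-first (long bouts need long free gaps,
    # which only exist early in the packing), redrawing starts that collide.
    order = sorted(range(len(pending)), key=lambda i: -pending[i][1])
    starts: list[float] = []  # sorted start times of placed events
    ends: list[float] = []  # ends, parallel to starts
    rows: list[tuple[str, float, float]] = []
    for idx in order:
        cls, dur = pending[idx]
        dur = min(dur, total_s / 2)
        placed = False
        for _ in range(200):
            s = float(rng.uniform(0.0, total_s - dur))
            i = bisect.bisect_right(starts, s)
            if i > 0 and ends[i - 1] > s:
                continue
            if i < len(starts) and starts[i] < s + dur:
                continue
            starts.insert(i, s)
            ends.insert(i, s + dur)
            rows.append((cls, s, dur))
            placed = True
            break
        if not placed:
            raise ValueError("rates too high: could not place event without overlap")

    log = pd.DataFrame(rows, columns=["class", "start_s", "duration_s"])
    log = log.sort_values("start_s", ignore_index=True)

    event_times = {
        cls: log.loc[log["class"] == cls, "start_s"].to_numpy()
        for cls in sorted(spec.rates_per_hour)
    }
    truth = SyntheticTruth(
        event_times=event_times,
        true_parameters={
            "rates_per_hour": dict(spec.rates_per_hour),
            "mean_event_duration_s": dict(spec.mean_event_duration_s),
            "total_hours": spec.total_hours,
            "seed": spec.seed,
        },
    )
    return log, truth
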