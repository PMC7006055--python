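"""Alternating extrema detection for cyclic kinematic traces.

Wraps :func:`scipy.signal.find_peaks` (prominence-gated) and adds two things
the raw routine does not give:

* endpoint extrema — spliced clips start on a swallow event, i.e. at a cycle
  minimum, so the first sample of a clip is routinely a genuine "closed"
  event that an interior-only peak finder would drop;
* alternation enforcement — of two consecutive same-sense extrema the more
  extreme one is kept, so maxima and minima strictly alternate.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks


def detect_alternating_extrema(
    x: np.ndarray, prominence: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (maxima_indices, minima_indices), alternating, endpoint-aware."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)

    max_idx = list(find_peaks(x, prominence=prominence)[0])
    min_idx = list(find_peaks(-x, prominence=prominence)[0])

    interior = sorted((i, +1) for i in max_idx) + sorted((i, -1) for i in min_idx)
    interior.sort()

    def _endpoint_ok(cand: int, kind: int, neighbor: int) -> bool:
        # one-sided prominence against the adjacent opposite extremum ...
        swing = (x[neighbor] - x[cand]) if kind == -1 else (x[cand] - x[neighbor])
        if swing < prominence:
            return False
        # ... and the candidate must reach the level of interior extrema of
        # the same sense (a clip cut mid-phase must not mint a false event).
        # One-sided: being *more* extreme than the interior level is fine;
        # the band of one prominence unit covers worst-case sampling
        # quantization of a genuine boundary extremum.
        same = min_idx if kind == -1 else max_idx
        if same:
            level = float(np.median(x[np.asarray(same)]))
            dev = (x[cand] - level) if kind == -1 else (level - x[cand])
            if dev > prominence:
                return False
        return True

    if interior:
        first_i, first_kind = interior[0]
        if first_kind == +1 and first_i > 0:  # first interior is a max
            cand = int(np.argmin(x[:first_i]))
            if _endpoint_ok(cand, -1, first_i):
                min_idx.append(cand)
        elif first_kind == -1 and first_i > 0:
            cand = int(np.argmax(x[:first_i]))
            if _endpoint_ok(cand, +1, first_i):
                max_idx.append(cand)
        last_i, last_kind = interior[-1]
        if last_i < x.size - 1:
            seg = x[last_i + 1 :]
            if last_kind == +1:  # trailing segment ends in a min candidate
                cand = last_i + 1 + int(np.argmin(seg))
                if _endpoint_ok(cand, -1, last_i):
                    min_idx.append(cand)
            else:
                cand = last_i + 1 + int(np.argmax(seg))
                if _endpoint_ok(cand, +1, last_i):
                    max_idx.append(cand)
    else:
        # no interior structure: a monotone ramp still has one of each
        lo, hi = int(np.argmin(x)), int(np.argmax(x))
        if x[hi] - x[lo] >= prominence and lo != hi:
            max_idx.append(hi)
            min_idx.append(lo)

    events = sorted(
        [(i, +1) for i in set(max_idx)] + [(i, -1) for i in set(min_idx)]
    )
    # enforce strict alternation: keep the more extreme of same-kind runs
    kept: list[tuple[int, int]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            j, _ = kept[-1]
            better = x[i] > x[j] if kind == +1 else x[i] < x[j]
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    maxima = np.array([i for i, k in kept if k == +1], dtype=int)
    minima = np.array([i for i, k in kept if k == -1], dtype=int)
    return maxima, minima


def default_prominence(x: np.ndarray, fraction: float = 0.2) -> float:
    """Default prominence threshold: a fraction of the trace's range."""
    x = np.asarray(x, dtype=float)
    return fraction * float(np.ptp(x)) if x.size else 0.0
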