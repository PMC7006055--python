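"""Seeding policy for the synthetic generators.

All generator randomness flows from one integer seed through a counter-based
bit generator (Philox), so the same seed yields the same output on any
platform or thread layout.
"""

from __future__ import annotations

import numpy as np


def make_rng(seed: int) -> np.random.Generator:
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    return np.random.Generator(np.random.Philox(int(seed)))
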