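import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from swallowkit.synthetic import (
    GlottalTraceSpec,
    JawTraceSpec,
    gen_glottal_traces,
    gen_jaw_trace,
)


@pytest.fixture
def clean_jaw_8hz():
    """Noise-free 8 Hz drinking clip: 16 full cycles in 2 s at 30 fps."""
    spec = JawTraceSpec(
        lick_rate_hz=8.0,
        amplitude_mm=0.79,
        duration_s=2.0,
        fps=30.0,
        noise_sd_mm=0.0,
        swallow_every_n_licks=4,
        ptt_frames=3,
        seed=0,
    )
    return gen_jaw_trace(spec)


@pytest.fixture
def clean_glottal_150():
    """Noise-free anti-phase breathing clip: 25 cycles in 10 s."""
    spec = GlottalTraceSpec(
        respiratory_rate_per_min=150.0,
        duration_s=10.0,
        fps=30.0,
        noise_sd_px=0.0,
        seed=0,
    )
    return gen_glottal_traces(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
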