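"""Shared fixtures: small synthetic sessions with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from ripplemap import core, synthio


@pytest.fixture(scope="session")
def small_session():
    """60 s LFP session with 20 injected ripples at 8x SD."""
    cfg = synthio.SynthConfig(duration=60.0, seed=1, ripple_amp=8.0)
    truth = synthio.sample_ripple_times(cfg, 20)
    lfp = synthio.generate_lfp(cfg, truth)
    return cfg, truth, lfp


@pytest.fixture(scope="session")
def three_region_atlas():
    return core.grid_atlas((24, 24), ["RSC", "PtA", "V1"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
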