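import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from primpulse import SynthSpec, make_video


@pytest.fixture(scope="session")
def short_video():
    """20 s noise-free-ish static recording at 120 BPM (2 Hz)."""
    spec = SynthSpec(hr_bpm=120.0, duration_s=20.0, noise_std=0.0, illum_drift=(0.0, 0.1), seed=11)
    return make_video(spec)


@pytest.fixture(scope="session")
def noisy_video():
    """40 s noisy static recording at 126 BPM."""
    spec = SynthSpec(hr_bpm=126.0, duration_s=40.0, noise_std=2.0, seed=5)
    return make_video(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
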