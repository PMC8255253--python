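import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from ivusgate import FrameSequence, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_stack(rng):
    """A small random grayscale stack for I/O and motion-signal tests."""
    frames = rng.integers(0, 256, size=(20, 8, 8), dtype=np.uint8)
    return FrameSequence(frames=frames, fps=30.0, vessel_type="LAD", id="tiny")


@pytest.fixture
def trace_config():
    """Fast signal-only simulation: regular 25-frame cycles, light noise."""
    return SyntheticConfig(
        n_frames=1000, fps=30.0, hr_mean=72.0, hr_jitter=0.0, noise_sigma=0.05, seed=7
    )
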