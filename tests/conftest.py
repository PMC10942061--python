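import numpy as np
import pytest

from betacal import synth
from betacal.io_stack import FrameStack


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_stack(rng):
    """Random 10-frame 16x16 uint16 movie."""
    return FrameStack(rng.integers(0, 4000, size=(10, 16, 16)).astype(np.uint16))


def oscillating_movie(seed: int = 0, amplitude: float = 0.5, read_noise_sd: float = 0.0):
    """A movie where every cell spikes three times at well-separated frames.

    This is the end-to-end fixture: the oscillating phenotype keeps spiking
    cells inside the pooled |Z| <= 3 band during outlier removal.
    """
    schedule = tuple(
        synth.SpikeEvent(c, f, amplitude)
        for c in range(1, 21)
        for f in (5 + c % 3, 12 + c % 3, 19 + c % 3)
    )
    params = synth.SynthParams(
        spike_schedule=schedule, seed=seed, read_noise_sd=read_noise_sd
    )
    return synth.generate_movie(params), params


@pytest.fixture
def clean_oscillating_movie():
    return oscillating_movie(seed=0)
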