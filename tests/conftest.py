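import numpy as np
import pytest

import erspkit as ek
from erspkit.cluster import SubjectDifference


@pytest.fixture(scope="session")
def layout62():
    return ek.make_layout(62)


@pytest.fixture(scope="session")
def layout3():
    return ek.make_layout(3)


def make_diff(rng, layout, freqs, times, subject_id="s", group="A", shift=0.0):
    """Random subject difference field (iid normal) with optional offset."""
    data = rng.standard_normal((layout.n_channels, len(freqs), len(times))) + shift
    return SubjectDifference(subject_id, group, data,
                             tuple(layout.channel_names), freqs, times)


@pytest.fixture(scope="session")
def small_grid():
    return ek.FrequencyGrid(3.0, 12.0, 0.5)


@pytest.fixture(scope="session")
def sine_epochs(layout3):
    """Two identical trials of a pure 10 Hz unit-amplitude sinusoid."""
    cfg = ek.SimulationConfig(seed=0, effects=())
    t = (np.arange(cfg.n_samples) - cfg.t0_index) / cfg.sfreq
    sig = np.cos(2 * np.pi * 10.0 * t)
    data = np.tile(sig, (2, 3, 1))
    return ek.EpochSet("sine", "A", "S1", data, cfg.sfreq, cfg.t0_index, layout3)
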