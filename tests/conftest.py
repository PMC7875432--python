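import numpy as np
import pytest

import splitsort as ss


@pytest.fixture(scope="session")
def spike_set():
    """Small labeled spike set: 3 classes x 200 spikes, mild noise."""
    return ss.generate_spikes(
        ss.SynthConfig(n_classes=3, n_per_class=200, noise_sd=0.05,
                       amp_jitter_sd=0.05, seed=3))


@pytest.fixture(scope="session")
def pca10(spike_set):
    return ss.pca_features(spike_set.waveforms, mode="fixed", m=10)


@pytest.fixture(scope="session")
def blobs2():
    """Two far-separated 2-D blobs with labels."""
    X, y = ss.generate_feature_mixture(k=2, dim=2, separation=20, n_per=50,
                                       sd=1.0, seed=0)
    return X, y


def schedule_clock(raw_times):
    """Fake clock yielding (0, t_i) pairs so probe i measures raw_times[i]."""
    seq = iter([v for t in raw_times for v in (0.0, float(t))])
    return lambda: next(seq)


@pytest.fixture
def make_clock():
    return schedule_clock
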