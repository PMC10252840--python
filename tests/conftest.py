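import numpy as np
import pytest

from stresspipe import synthetic as syn


@pytest.fixture(scope="session")
def tiny_sim_config() -> syn.SimConfig:
    """Small but spectrally faithful: 3 subjects x 20 s x 14 channels."""
    return syn.SimConfig(n_subjects=3, duration=20.0, seed=1234)


@pytest.fixture(scope="session")
def tiny_recordings(tiny_sim_config):
    return [
        syn.generate_recording(tiny_sim_config, s, c)
        for s in range(1, tiny_sim_config.n_subjects + 1)
        for c in syn.CONDITIONS
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def separable_windows():
    """Linearly separable toy windows: constant-offset noise, 200 samples."""
    r = np.random.default_rng(7)
    n, t = 200, 64
    X = np.concatenate(
        [r.normal(-1.0, 0.3, (n // 2, t, 1)), r.normal(1.0, 0.3, (n // 2, t, 1))]
    )
    y = np.concatenate([np.zeros(n // 2), np.ones(n // 2)]).astype(np.int64)
    perm = r.permutation(n)
    return X[perm], y[perm]
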