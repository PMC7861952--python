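import numpy as np
import pytest

import emgfuse as ef


@pytest.fixture(scope="session")
def toy_table():
    """Far-separated 3-class blobs: 20 rows/class, 5 features, one discrete."""
    return ef.make_toy_multiclass(20, 3, 5, separation=10.0, discrete_cols={2}, seed=11)


@pytest.fixture(scope="session")
def small_emg():
    """2 subjects x 3 classes x 6 repetitions, 2 channels, 1 s trials at 2 kHz."""
    spec = ef.EmgSimSpec(
        n_subjects=2,
        n_classes=3,
        n_channels=2,
        n_repetitions=6,
        trial_duration=1.0,
        rest_duration=1.0,
        seed=7,
    )
    return ef.simulate_emg_dataset(spec)


@pytest.fixture(scope="session")
def emg_cv_results(small_emg):
    """One threefold CV run of the full pipeline on the simulated recordings
    (shrunken test profile), shared by the structural and leakage checks."""
    cfg = ef.PipelineConfig.test_profile(seed=7)
    cfg.spectrogram = ef.SpectrogramSpec(window_ms=200, increment_ms=100, n_fft=512)
    cfg.autoencoder.max_epochs = 80
    return ef.GestureFusionModel(small_emg, cfg).fit(7)
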