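import numpy as np
import pytest

import opticalmi as om


@pytest.fixture(scope="session")
def mi_config():
    """Separable study conditions: 8 channels, 100 Hz, 2 s trials."""
    return om.SyntheticConfig(
        n_channels=8,
        fs=100.0,
        n_trials_per_class=30,
        power_ratio=4.0,
        snr=3.0,
        mixing_seed=11,
        noise_seed=12,
    )


@pytest.fixture(scope="session")
def mi_small(mi_config):
    return om.generate_mi_dataset(mi_config)


@pytest.fixture(scope="session")
def mi_small_pp(mi_small):
    return om.preprocess_dataset(mi_small)


@pytest.fixture(scope="session")
def fitted_small(mi_small_pp):
    """One fused predictor trained on the small preprocessed dataset."""
    return om.OpticalModel(mi_small_pp).fit(seed=0)


@pytest.fixture(scope="session")
def nontask_small(mi_config):
    return om.generate_nontask_trials(mi_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
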