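import numpy as np
import pytest

from avtrack.synthetic import default_truth, generate_dataset


@pytest.fixture(scope="session")
def noiseless_lip_dataset():
    """60 s noiseless dataset driven only by the lip kernel (independent
    lip feature), for clean deconvolution checks."""
    truth = default_truth(
        seed=11,
        noise_sd=0.0,
        av_correlation=0.0,
        condition_gains={"single": 1.0, "multi": 2.0},
    )
    truth.kernels["spectrogram"][:] = 0.0
    truth.kernels["onsets"][:] = 0.0
    return generate_dataset(2, 3, 60.0, truth)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """Small noisy dataset with all three features active."""
    truth = default_truth(seed=21, noise_sd=1.0)
    return generate_dataset(3, 4, 40.0, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
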