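import numpy as np
import pytest

from diffsem.simulate import simulate_paired_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy paired dataset with ground truth (p=5, n=80)."""
    rng = np.random.default_rng(777)
    return simulate_paired_dataset(
        p=5, n=80, n_e=1, sigma2=0.01, kind="dag", rng=rng
    )


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free paired dataset: the SEM identity holds exactly."""
    rng = np.random.default_rng(778)
    return simulate_paired_dataset(
        p=4, n=30, n_e=1, sigma2=0.0, kind="dag", rng=rng
    )
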