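import numpy as np
import pytest

from tacfit import DatasetSpec, ExperimentConfig, generate_dataset, train_chain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """60 + 60 noisy curves with 8 points each (shared, read-only)."""
    return generate_dataset(DatasetSpec(8, 60, 60, 0.05, seed=7))


@pytest.fixture(scope="session")
def small_clean_dataset():
    """200 + 200 noise-free training curves with 8 points each."""
    return generate_dataset(DatasetSpec(8, 200, 200, 0.0, seed=11))


@pytest.fixture(scope="session")
def tiny_config():
    """A fast ExperimentConfig for end-to-end plumbing tests."""
    return ExperimentConfig(
        n_set=(6,),
        train_me=120, train_be=120,
        test_me=40, test_be=40,
        seed=5,
        regressor_params={"gbr_n_estimators": 25, "ada_n_estimators": 2},
    )


@pytest.fixture(scope="session")
def tiny_chain(tiny_config):
    return {6: train_chain(tiny_config, 6)}
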