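import numpy as np
import pytest

from pesuq.backbone import TrainConfig, train_model
from pesuq.toysystem import SamplerConfig, ToyPES, default_params, make_benchmark


@pytest.fixture(scope="session")
def toy_pes() -> ToyPES:
    """Calibrated default toy PES (barrier 20, asymmetry +5 kcal/mol)."""
    return ToyPES(default_params())


@pytest.fixture(scope="session")
def small_benchmark(toy_pes):
    """A small train/validation + test benchmark with ground-truth OOD flags."""
    config = SamplerConfig(n_samples=400, seed=7)
    trainval, test, flags = make_benchmark(
        toy_pes, config, n_test_id=150, n_test_ood=40,
        test_temperatures=(300.0, 300.0, 500.0),
    )
    return trainval, test, flags


@pytest.fixture(scope="session")
def quick_train_config() -> TrainConfig:
    """Small network / fast optimizer settings for unit tests."""
    return TrainConfig(
        hidden=(32, 32),
        max_epochs=400,
        batch_size=32,
        learning_rate=3e-3,
        early_stopping_patience=100,
    )


@pytest.fixture(scope="session")
def trained_scalar_model(small_benchmark, quick_train_config):
    trainval, _, _ = small_benchmark
    return train_model(trainval, quick_train_config, head="scalar", seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
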