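import numpy as np
import pytest

from p300speller import (
    ClassifierSpec,
    SimulationConfig,
    SymbolMatrix,
    generate_dataset,
    train_strategy,
)


@pytest.fixture(scope="session")
def matrix():
    return SymbolMatrix()


@pytest.fixture(scope="session")
def small_dataset():
    """Small labeled dataset at default SNR (beta=4, default 6x6 / alpha=15)."""
    return generate_dataset(SimulationConfig(beta=4, seed=11))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Very small paradigm (n=m=2, alpha=3, 4 channels) for fast structural tests."""
    cfg = SimulationConfig(n=2, m=2, alpha=3, beta=6, n_channels=4, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def lda_strategy(small_dataset):
    """Single-LDA strategy trained on the small default-SNR dataset."""
    return train_strategy(small_dataset, "single", ClassifierSpec("lda", seed=0))


@pytest.fixture(scope="session")
def separable_features():
    """Linearly separable 2-cluster feature set mimicking target/nontarget epochs."""
    rng = np.random.default_rng(3)
    X0 = rng.normal(0.0, 0.3, size=(60, 20))
    X1 = rng.normal(2.0, 0.3, size=(60, 20))
    X = np.vstack([X0, X1])
    labels = ["nontarget"] * 60 + ["target"] * 60
    return X, labels
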