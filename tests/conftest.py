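import numpy as np
import pytest

from taxalist import (
    LISTModel,
    SimConfig,
    fig_fixture,
    gen_labeled_dataset,
    train_model,
)


@pytest.fixture(scope="session")
def fig():
    """Canonical toy MSA: (query, msa, shared-taxa index)."""
    return fig_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """Quick strong-contrast benchmark (~500 labeled positions)."""
    return gen_labeled_dataset(SimConfig(seed=7, n_proteins=30, protein_length=150))


@pytest.fixture(scope="session")
def small_model(small_dataset) -> LISTModel:
    ds = small_dataset
    return train_model(ds.msas, ds.st_index, ds.train)


@pytest.fixture(scope="session")
def big_dataset():
    """Strong-contrast benchmark with ~5,000 labeled positions."""
    return gen_labeled_dataset(SimConfig(seed=3, n_proteins=264, protein_length=200))


@pytest.fixture(scope="session")
def big_model(big_dataset) -> LISTModel:
    ds = big_dataset
    return train_model(ds.msas, ds.st_index, ds.train)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
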