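import numpy as np
import pytest

from pupsite import synthetic_data
from pupsite.model import PupylationSiteModel


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-motif dataset: 20 proteins x 2 sites (40 positives)."""
    return synthetic_data.generate(n_proteins=20, seed=11)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    return PupylationSiteModel.from_synthetic(small_dataset, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
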