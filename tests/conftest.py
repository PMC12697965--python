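import warnings

import numpy as np
import pytest

from obslearn.hier_fit import fit_hierarchical
from obslearn.synthetic_data import StudyDesign, generate_study

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(n_participants=10, n_blocks=2, seed=11)


@pytest.fixture(scope="session")
def small_study(small_design):
    """A desk-scale synthetic study generated from the full model."""
    return generate_study(small_design, "full")


@pytest.fixture(scope="session")
def small_full_fit(small_study):
    """A reduced-scale hierarchical full-model fit, shared across tests."""
    dataset, _ = small_study
    return fit_hierarchical(dataset, "full", chains=4, warmup=200, draws=200, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
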