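import numpy as np
import pytest

from hotspotsurv.maf_io import mutations_from_frame, survival_from_frame
from hotspotsurv.synthetic_data import figure1_toy


@pytest.fixture(scope="session")
def fig1_records():
    """The deterministic 54-patient walkthrough cohort, already normalized."""
    maf, clinical, truth = figure1_toy()
    mutations = mutations_from_frame(maf)
    survival = survival_from_frame(clinical)
    return mutations, survival, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240306)
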