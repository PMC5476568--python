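import numpy as np
import pytest

from infoshare.montage import build_montage
from infoshare.simulate import CohortDesign


@pytest.fixture(scope="session")
def m1020():
    return build_montage("standard1020")


@pytest.fixture(scope="session")
def dense():
    return build_montage("dense128")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_design():
    """Desk-scale cohort design for fast structural tests."""
    return CohortDesign(
        n_patients=9,
        n_controls=9,
        epochs_per_subject=4,
        epoch_len_s=1.0,
        seed=42,
    )
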