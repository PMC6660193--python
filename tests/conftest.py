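import numpy as np
import pytest

from poreblock.constants import DEFAULT_CONSTANTS
from poreblock.state_model import SchemeParams


@pytest.fixture
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture
def scheme_10k():
    """Fitted scheme for the low-ionic-strength 10 mM K+ condition."""
    return SchemeParams(
        kdc=1.84, kdo0=1.7, z_tox=0.29, z_gate=3.9, v_half=-66.0, toxin_conc=5.0
    )


@pytest.fixture
def scheme_10na():
    """Fitted scheme for the low-ionic-strength 10 mM Na+ condition."""
    return SchemeParams(
        kdc=2.81, kdo0=3.9, z_tox=0.36, z_gate=4.0, v_half=-67.0, toxin_conc=5.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
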