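import numpy as np
import pytest

from coevonet.alignment import Alignment
from coevonet.geometry import ideal_helix


@pytest.fixture
def toy_alignment() -> Alignment:
    """Four sequences, five columns, mixed conservation and covariation."""
    return Alignment(
        ids=["a", "b", "c", "d"],
        rows=["ALKGD", "ALKGE", "RVKAD", "RVKAE"],
    )


@pytest.fixture
def gapped_alignment() -> Alignment:
    return Alignment(
        ids=["a", "b", "c", "d"],
        rows=["AR-KD", "AK-KE", "A--RD", "GRAR-"],
    )


@pytest.fixture(scope="session")
def helix12():
    return ideal_helix(12)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
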