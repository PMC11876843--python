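import numpy as np
import pytest

from enhancersyntax.motifs import Motif
from enhancersyntax.simulate import make_motif_set


@pytest.fixture
def simple_motif():
    """Width-4 motif with consensus ACGT and a clear dominant base."""
    counts = np.array(
        [
            [8, 1, 1, 0],
            [0, 9, 1, 0],
            [1, 0, 8, 1],
            [0, 1, 1, 8],
        ],
        dtype=float,
    )
    return Motif(tf_name="TEST", motif_id="T0001", counts=counts)


@pytest.fixture(scope="session")
def motif_set():
    return make_motif_set(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
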