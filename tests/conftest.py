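import numpy as np
import pytest

from ergtwin.cohort import CohortSpec
from ergtwin.defaults import DEFAULT_GAINS
from ergtwin.protocols import protocol_by_label


@pytest.fixture(scope="session")
def gains():
    return DEFAULT_GAINS


@pytest.fixture(scope="session")
def by_label():
    return protocol_by_label()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A small, fast cohort for pipeline tests."""
    return CohortSpec(n_pairs=4, sweeps_per_stimulus=2, seed=99, artifact_rate=0.0)
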