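import numpy as np
import pytest

from vlobule.analysis_io import make_fixture_lobule
from vlobule.lobule import build_lobule


@pytest.fixture(scope="session")
def lobule():
    """One default-geometry Monte Carlo lobule shared across tests."""
    return build_lobule(seed=1234)


@pytest.fixture(scope="session")
def fixture_lobule():
    """Deterministic 6-segment miniature lobule with hand-checkable dPP values."""
    return make_fixture_lobule()


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
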