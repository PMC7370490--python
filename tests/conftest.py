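import numpy as np
import pytest

from cassettescan import build_default_model, reference_model
from cassettescan.scan import ScoringTables
from cassettescan.simulate import _random_seq, make_attc_site


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def trained_model():
    """Working model trained on 231 simulated annotated sites."""
    return reference_model(seed=0)


@pytest.fixture(scope="session")
def default_tables(default_model):
    return ScoringTables.from_model(default_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n, gc=0.5):
    return _random_seq(rng, n, gc)


def perfect_site(rng):
    """One unmutated attC site plus its segment lengths."""
    return make_attc_site(rng, 0.5, 0.0)
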