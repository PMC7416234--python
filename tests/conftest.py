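import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mipso import MSTConfig, PSOConfig, extract_features, make_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    """40 trials x 8 channels x 1 s, two informative channels."""
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_features(tiny_fixture):
    return extract_features(tiny_fixture.train, MSTConfig())


@pytest.fixture
def small_pso():
    return PSOConfig(n_particles=12, n_iterations=15, seed=0)
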