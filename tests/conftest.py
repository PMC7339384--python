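import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from trfphas.fixtures import load_published_tables
from trfphas.synth import SimConfig, simulate_trna_set


@pytest.fixture(scope="session")
def published():
    return load_published_tables()


@pytest.fixture(scope="session")
def trna_set():
    return simulate_trna_set(SimConfig(seed=11, n_trnas=8))


@pytest.fixture()
def base_config():
    return SimConfig(seed=5)
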