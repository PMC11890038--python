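import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kmerpop import scenario_library, simulate, write_fasta


@pytest.fixture(scope="session")
def three_pop_samples():
    """Scaled three-population scenario, well separated (long divergence)."""
    return simulate(scenario_library("three-pop", scale=0.01, seed=0))


@pytest.fixture(scope="session")
def three_pop_manifest(three_pop_samples, tmp_path_factory):
    """FASTA directory + manifest for the scaled three-population fixture."""
    out = tmp_path_factory.mktemp("three_pop")
    return write_fasta(three_pop_samples, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
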