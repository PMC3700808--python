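import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/helpers.py importable

from spliceshield.simulate import SimConfig, simulate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic input bundle shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(n_genes=6, seed=11)
    simulate_dataset(cfg, out)
    return out
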