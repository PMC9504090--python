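import numpy as np
import pytest

from pnvf import synth
from pnvf.config import PipelineConfig


@pytest.fixture(scope="session")
def anatomy():
    """Default-grid phantom shared across tests."""
    return synth.make_phantom_anatomy((24, 24, 18), n_networks=3, seed=1)


@pytest.fixture(scope="session")
def small_anatomy():
    return synth.make_phantom_anatomy((16, 16, 12), n_networks=3, seed=1,
                                      network_radius_vox=2.5,
                                      min_separation_vox=6.0)


@pytest.fixture(scope="session")
def spec():
    return synth.CohortSpec()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
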