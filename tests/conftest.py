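import warnings

import numpy as np
import pytest

from sonata import ModalityData, RunConfig, diagnose, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_t_pair():
    """Scaled-down T-branch pair for fast module-level tests."""
    return simulate("t_branch", n=150, px=80, py=100, seed=0)


@pytest.fixture(scope="session")
def small_decay_pair():
    return simulate("decay_path", n=150, px=80, py=100, seed=0)


@pytest.fixture(scope="session")
def small_t_report(small_t_pair):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return diagnose(small_t_pair.modality_x, RunConfig(seed=0))


@pytest.fixture
def random_modality(rng):
    return ModalityData(rng.normal(size=(40, 6)))
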