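import numpy as np
import pytest

import fusednet as fn


@pytest.fixture(scope="session")
def head64():
    """Small toy head model shared across tests: 16 sensors, 64 dipoles."""
    head, lead = fn.make_head_model(16, 64)
    return head, lead


@pytest.fixture(scope="session")
def head200():
    """Default-size geometry: 16 sensors, 200 dipoles."""
    head, lead = fn.make_head_model(16, 200)
    return head, lead


@pytest.fixture(scope="session")
def epoch_time_axis():
    return fn.StudyConfig().time_axis()


@pytest.fixture(scope="session")
def tiny_study():
    """One-subject study at reduced size, for end-to-end module tests."""
    cfg = fn.StudyConfig(
        n_subjects=1, n_trials=6, n_sources=100, n_voxels=150, n_volumes=100
    )
    return fn.generate_study(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
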