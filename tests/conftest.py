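import numpy as np
import pytest

from qmritrack.phantom import PhantomConfig, generate_phantom
from qmritrack.protocol import AcquisitionProtocol


@pytest.fixture(scope="session")
def small_angle_protocol():
    return AcquisitionProtocol.small_angle()


@pytest.fixture(scope="session")
def clean_phantom():
    """One noiseless subject: exact truth maps, no jitter."""
    cfg = PhantomConfig(
        n_subjects=1,
        seed=5,
        map_noise_frac=0.0,
        visit_sd_frac=0.0,
        noise_sd=0.0,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_phantom():
    """A small but complete two-subject cohort with noise."""
    cfg = PhantomConfig(n_subjects=2, seed=3, grid_shape=(40, 46, 40))
    return generate_phantom(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
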