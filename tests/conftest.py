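import numpy as np
import pytest

from exstate import synthetic


@pytest.fixture(scope="session")
def truth():
    """Default two-state study conditions (seed 0)."""
    return synthetic.make_paperlike_truth(seed=0)


@pytest.fixture(scope="session")
def null_truth():
    """One-state negative control."""
    return synthetic.make_one_state_truth(seed=0)


@pytest.fixture(scope="session")
def rdc_records(truth):
    return synthetic.simulate_rdc_sets(truth)


@pytest.fixture(scope="session")
def dispersion_records(truth):
    return synthetic.simulate_dispersion(truth)


@pytest.fixture(scope="session")
def small_backbone():
    """Short idealized chain for cheap geometry tests."""
    ground, _ = synthetic.make_two_state_structures(
        n_residues=24, displaced_segments=((8, 16),), tilt_angle_deg=0.0,
        seed=0)
    return ground


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
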