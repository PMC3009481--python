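import numpy as np
import pytest

from npca_protpat.data import IntensityMatrix
from npca_protpat.simulate import SyntheticSpec, generate_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_profiles():
    """Labeled 20+20 x 120 synthetic dataset with 5 planted markers."""
    spec = SyntheticSpec(n_per_class=(20, 20), n_features=120, n_markers=5,
                         effect_size=2.5, seed=42)
    return generate_profiles(spec)


@pytest.fixture
def tiny_matrix():
    values = np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 6.0]])
    mz = np.array([900.1, 950.2, 1000.3])
    return IntensityMatrix(values, mz)
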