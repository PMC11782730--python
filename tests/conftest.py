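import numpy as np
import pytest

from b1net.phantom import generate_library
from b1net.model import normalize_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_library():
    """Small paired library: 4 subjects, 32x32 grid, 2 slices/orientation."""
    return generate_library(
        n_subjects=4,
        slices_per_orientation=2,
        snr=50.0,
        seed=77,
        shape=(32, 32),
        spacing=0.006,
    )


@pytest.fixture(scope="session")
def tiny_library_normalized(tiny_library):
    lib, scales = normalize_dataset(tiny_library)
    return lib, scales
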