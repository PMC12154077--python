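import numpy as np
import pytest

from admixer.phantoms import generate_dataset


@pytest.fixture(scope="session")
def tiny_set():
    """Small 5-class phantom set shared by fast tests."""
    return generate_dataset([6, 6, 6, 6, 6], image_size=64, seed=11, noise_sigma=0.02)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
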