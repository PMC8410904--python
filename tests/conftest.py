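import numpy as np
import pytest

from cephalorl import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with analytically known landmarks."""
    return generate_phantom(PhantomSpec(noise_sigma=0.0), seed=11)


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
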