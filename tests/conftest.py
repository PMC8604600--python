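import numpy as np
import pytest

from medihash import ChaosKey, generate_test_image


@pytest.fixture(scope="session")
def key() -> ChaosKey:
    return ChaosKey.from_passphrase("correct horse battery staple")


@pytest.fixture(scope="session")
def image() -> np.ndarray:
    return generate_test_image(1)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
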