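import numpy as np
import pytest

from nedsem.synthetic import LesionSpec, generate


@pytest.fixture(scope="session")
def default_phantom():
    """The default 128×128 lesion phantom and its ground truth."""
    return generate(LesionSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """A harder phantom: stronger noise plus hair and bubble artifacts."""
    spec = LesionSpec(noise_sigma=8.0, hair_count=8, bubble_count=4, seed=1)
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
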