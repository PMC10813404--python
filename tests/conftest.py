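import numpy as np
import pytest

from funduskit.synthetic import generate_fundus, spec_for_grade


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def normal_sample():
    """A clean (noise-free) normal-grade synthetic fundus, 96x96."""
    return generate_fundus(spec_for_grade("normal", seed=7, width=96, height=96,
                                          noise_sd=0.0))


@pytest.fixture(scope="session")
def malignant_sample():
    return generate_fundus(spec_for_grade("malignant", seed=11, width=128,
                                          height=128, noise_sd=0.0))


@pytest.fixture(scope="session")
def severe_sample():
    return generate_fundus(spec_for_grade("severe", seed=5, width=96, height=96,
                                          noise_sd=0.01))
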