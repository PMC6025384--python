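import numpy as np
import pytest

from roughmri.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def abnormal_phantom():
    return generate_phantom(PhantomSpec(class_label="abnormal", seed=43))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
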