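import numpy as np
import pytest

import wmhkit.nn.autodiff as autodiff
from wmhkit.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def float64_autodiff():
    """Run autodiff in double precision (for finite-difference checks)."""
    saved = autodiff.DEFAULT_DTYPE
    autodiff.DEFAULT_DTYPE = np.float64
    yield
    autodiff.DEFAULT_DTYPE = saved


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(shape=(12, 64, 64), spacing=(5.0, 2.0, 2.0),
                       n_wmh_lesions=5, n_other_lesions=2, seed=42)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec)
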