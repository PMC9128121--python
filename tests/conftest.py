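import numpy as np
import pytest

from bearmove import GridSpec, default_class_params, make_covariate_stack


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_stack():
    """A 56x56, 40-day covariate stack shared by fast tests."""
    return make_covariate_stack(
        GridSpec(0.0, 0.0, 25_000.0, 56, 56), 40, np.random.default_rng(99)
    )


@pytest.fixture(scope="session")
def af_params():
    return default_class_params()["AF"]
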