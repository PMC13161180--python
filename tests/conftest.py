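import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 labeled phantom with 2% lesion load (session-wide, read-only)."""
    from qqoef.phantom import make_phantom

    return make_phantom((32, 32, 32), lesion_load=0.02, seed=7)


@pytest.fixture(scope="session")
def default_const():
    from qqoef.phantom import PhysioConstants

    return PhysioConstants()


@pytest.fixture(scope="session")
def small_acq():
    from qqoef.phantom import AcquisitionParams

    return AcquisitionParams(matrix_size=(32, 32, 32))
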