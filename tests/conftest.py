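import numpy as np
import pytest

from jointpet.synthetic import PhantomSpec, make_joint_phantom

# small, fast phantom grid used throughout the unit tests; the geometry
# (all in mm) is identical to the default full-size phantom
SMALL_GRID = dict(shape=(64, 64, 96), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def knee_phantom():
    return make_joint_phantom(PhantomSpec(joint="knee", seed=11, **SMALL_GRID))


@pytest.fixture(scope="session")
def hip_phantom():
    return make_joint_phantom(PhantomSpec(joint="hip", seed=12, **SMALL_GRID))


@pytest.fixture(scope="session")
def si_phantom():
    return make_joint_phantom(PhantomSpec(joint="si", seed=13, **SMALL_GRID))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230901)
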