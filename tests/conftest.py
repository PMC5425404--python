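import numpy as np
import pytest

from vascusim.geometry import make_cuboid, make_cylinder, make_hemisphere_shell


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def shell():
    return make_hemisphere_shell((0.0, 0.0, 0.0), 1400.0, 100.0)


@pytest.fixture
def roi_cylinder():
    return make_cylinder((0.0, 0.0, 0.0), 600.0, 200.0, (0, 0, 1))


@pytest.fixture
def pellet():
    return make_cuboid((-150.0, -150.0, 1300.0), (300.0, 300.0, 100.0))
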