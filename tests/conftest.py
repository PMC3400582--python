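import numpy as np
import pytest

from wormscreen import synthetic
from wormscreen.types import PlateCondition, WormShapeSpec

# small-well geometry used across imaging tests: enough room for a dozen
# animals while keeping a single well render around 250x250 px
SMALL_SPEC = WormShapeSpec(count=12, backbone_length=50, body_width=8,
                           min_separation=4)
SMALL_RADIUS = 110.0


@pytest.fixture(scope="session")
def small_truth():
    return synthetic.simulate_worm_shapes(SMALL_SPEC, SMALL_RADIUS, seed=11)


@pytest.fixture(scope="session")
def induced_condition():
    return PlateCondition(strain="sj4005", rnai_clone="vector",
                          treatment="tunicamycin", induction_factor=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
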