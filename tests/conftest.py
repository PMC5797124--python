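import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import iscmix as im

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """6/6/6 cohort on a 4x4 toy mesh; adult coupling 0.6 in effect nodes."""
    cfg = im.SyntheticCohortConfig(
        n_per_group={"child4": 6, "child6": 6, "adult": 6},
        mesh_spec=(4, 4, 3.0),
        seed=11,
    )
    return im.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_isc(small_cohort):
    """ISC matrix of the small cohort on mean-100-scaled (unfiltered) data."""
    scaled = [im.scale_to_mean_100(s) for s in small_cohort.subjects]
    return im.pairwise_isc(scaled)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
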