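import numpy as np
import pytest

from conntensor import worked_fixture
from conntensor.simulate import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Deterministic 12-subject, 6-node cohort with planted effects."""
    cohort, truth = worked_fixture()
    return cohort, truth


@pytest.fixture(scope="session")
def two_group_cohort():
    """Moderate synthetic AD-vs-NC cohort used by several harness tests."""
    spec = SyntheticSpec(
        n_per_group={"AD": 30, "NC": 30, "MCI": 1},
        p=20,
        base_rank=3,
        effect_edges=15,
        effect_size=1.5,
        noise_sd=0.1,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
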