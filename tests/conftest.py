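import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cohort_config():
    """A cohort small enough for fast end-to-end runs, 4 ROIs, 5 s series."""
    from painattn.simulate import CohortConfig

    return CohortConfig(
        n_subjects_per_group=3,
        seed=7,
        duration_s=5.0,
        roi_list=("PCC", "precuneus", "left_S1", "right_TPJ"),
        latent_p_range_by_group=((0.05, 0.2), (0.8, 0.95)),
    )
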