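import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from organoidtrack.imgproc import SegmentationParams
from organoidtrack.laws import Law
from organoidtrack.synthcohort import ArmSpec, ChannelParams, CohortSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_cohort_spec(
    n_per_arm=16,
    arms=None,
    seed=7,
    day4_jitter_um=5.0,
    attrition=0.0,
) -> CohortSpec:
    """A compact two-arm cohort on reduced-field geometry (fast to render)."""
    if arms is None:
        arms = (
            ArmSpec(
                "control",
                n_per_arm,
                d0_diameter_law=Law.lognormal(220.0, 0.12),
                growth_pct_law=Law.normal(60.0, 30.0),
                attrition=attrition,
            ),
            ArmSpec(
                "FOLFOX",
                n_per_arm,
                d0_diameter_law=Law.lognormal(220.0, 0.12),
                growth_pct_law=Law.normal(-10.0, 30.0),
                delta_orr_law=Law.normal(0.02, 0.03),
                attrition=attrition,
            ),
        )
    return CohortSpec(
        line_id="SYN1",
        arms=arms,
        fields_per_replicate=1,
        replicates=2,
        field_size_px=(768, 768),
        pixel_size_um=4.0,
        grid_pitch_px=192,
        day4_jitter_um=day4_jitter_um,
        seed=seed,
    )


@pytest.fixture
def cohort_spec():
    return small_cohort_spec()


@pytest.fixture
def noise_free_channels():
    return ChannelParams().noise_free()


@pytest.fixture
def seg_params():
    return SegmentationParams(min_area_um2=500.0)
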