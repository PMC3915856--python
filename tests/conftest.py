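import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from avfstudy import place_rois  # noqa: E402
from avfstudy.synthetic import (  # noqa: E402
    compartment_masks,
    default_calibration,
    small_phantom,
)

#: PLA rates scaled so that spot fields fit the reduced test phantom with the
#: same areal packing as the full-scale study phantom.
SMALL_PLA_RATES = {"endothelium": 6000.0, "media": 2500.0}


@pytest.fixture(scope="session")
def small_ph():
    return small_phantom()


@pytest.fixture(scope="session")
def small_seg(small_ph):
    return compartment_masks(small_ph)["segmentation"]


@pytest.fixture(scope="session")
def small_rois(small_ph, small_seg):
    return place_rois(small_seg, small_ph.pixel_size_um)


@pytest.fixture()
def small_profile():
    return default_calibration(seed=11, pla_base_rate_mm2=dict(SMALL_PLA_RATES))


def noise_free_profile(**overrides):
    """A replicate-noise-free calibration for exactness checks."""
    overrides.setdefault("replicate_noise_cv", 0.0)
    overrides.setdefault("pla_base_rate_mm2", dict(SMALL_PLA_RATES))
    return default_calibration(seed=5, **overrides)
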