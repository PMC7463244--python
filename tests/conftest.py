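import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import slidequant as sq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# small but geometrically valid study conditions for fast tests
SMALL_PARAMS = sq.SynthParams(
    slide_size_px=(512, 512),
    n_crypts=4,
    crypt_radius_um=(15.0, 3.0),
    epithelial_thickness_um=8.0,
    fov_size_px=(128, 128),
    seed=11,
)


@pytest.fixture(scope="session")
def default_slide():
    """One default-condition slide with ground truth (fixed seed)."""
    return sq.generate_slide(dataclasses.replace(sq.SynthParams(), seed=1))


@pytest.fixture(scope="session")
def small_slide():
    """A small, fast slide with ground truth."""
    return sq.generate_slide(SMALL_PARAMS)


@pytest.fixture
def small_params():
    return SMALL_PARAMS
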