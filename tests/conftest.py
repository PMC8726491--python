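import numpy as np
import pytest

from femhu import (
    MaskVolume,
    PhantomSpec,
    RegionGrowConfig,
    fill_interior,
    region_grow,
    render_phantom,
    sample_cohort,
)
from femhu.pipeline import find_seed_point


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced-scale phantom used where full resolution is not the point."""
    return PhantomSpec().scaled(0.75)


@pytest.fixture(scope="session")
def phantom_case(default_spec):
    """One rendered subject at full resolution with its truth channel."""
    profile = sample_cohort(1, 0, seed=11)[0]
    vol, truth = render_phantom(profile, default_spec, seed=42)
    return profile, vol, truth


@pytest.fixture(scope="session")
def segmented_femur(phantom_case):
    """The filled femur mask recovered by the segmentation chain."""
    _, vol, _ = phantom_case
    seed_pt = find_seed_point(vol, 126.0, 3071.0)
    grown = region_grow(vol, RegionGrowConfig(seed_pt))
    return fill_interior(grown)


def digital_ball(radius_vox: int, spacing=(1.0, 1.0, 1.0), pad: int = 2) -> MaskVolume:
    n = 2 * (radius_vox + pad) + 1
    c = radius_vox + pad
    ii, jj, kk = np.ogrid[:n, :n, :n]
    ball = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= radius_vox**2
    return MaskVolume(ball, spacing)
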