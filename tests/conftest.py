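import numpy as np
import pytest

from mnswell.geometry import (
    DEFAULT_SHAPES,
    DEFAULT_SWELL,
    RadialProfile,
    apply_swell,
    shape_profile,
)


@pytest.fixture(scope="session")
def default_profiles():
    """Pinned default shapes sampled at high resolution."""
    return {name: shape_profile(p, 2001) for name, p in DEFAULT_SHAPES.items()}


@pytest.fixture(scope="session")
def swollen_profiles(default_profiles):
    return {name: apply_swell(p, DEFAULT_SWELL) for name, p in default_profiles.items()}


@pytest.fixture
def cylinder_profile():
    """Uniform-radius profile: closed-form volume pi r^2 h."""
    return RadialProfile(x=np.array([0.0, 500.0]), r=np.array([100.0, 100.0]))
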