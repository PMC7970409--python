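"""Shared fixtures: small, fast scan geometries for unit tests.

The full validation geometry (100×100 grid, 15×50 beam positions) is only
exercised where a test is explicitly about it; everything else runs on a
coarse 32×32 grid with few beam positions.
"""

import numpy as np
import pytest

from xlct.forward import BeamSpec, DetectorSet
from xlct.phantoms import (OpticalProperties, PhantomConfig, SphericalTarget,
                           make_phantom)

SMALL_VOXEL = 25.0 / 32   # 32×32 slice grid over the 25 mm diameter


@pytest.fixture
def props():
    return OpticalProperties(mu_a=0.5, mu_s_prime=15.0)


@pytest.fixture
def small_beam():
    return BeamSpec(n_views=8, n_translations=16, translation_step=1.5)


@pytest.fixture
def detectors():
    return DetectorSet()


@pytest.fixture
def small_phantom():
    """One off-center 3 mm target on a coarse grid."""
    return make_phantom(
        targets=[SphericalTarget(center=(4.0, -2.0, 0.0), radius=3.0,
                                 concentration=1.0)],
        voxel_size=SMALL_VOXEL)


@pytest.fixture
def empty_phantom():
    return make_phantom(voxel_size=SMALL_VOXEL)


@pytest.fixture
def small_config():
    return PhantomConfig(voxel_size=SMALL_VOXEL)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
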