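"""Shared fixtures: small, seeded phantoms generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gfb3d.io_formats import ImageVolume
from gfb3d.phantom import (GfbPhantomSpec, SpacePhantomSpec, add_fiducials,
                           generate_blank_resin, generate_gfb_phantom,
                           generate_space_phantom)


@pytest.fixture(scope="session")
def small_gfb_spec() -> GfbPhantomSpec:
    """A reduced-field section: 144 nm thick, 264 nm wide, consistent layers."""
    return GfbPhantomSpec(
        volume_shape=(96, 176, 176),
        voxel_size=(1.5, 1.5, 1.5),
        glycocalyx_thickness=90.0,
        membrane_plane=114.0,
        endothelium_thickness=15.0,
        gbm_thickness=15.0,
    )


@pytest.fixture(scope="session")
def small_gfb_phantom(small_gfb_spec):
    return generate_gfb_phantom(small_gfb_spec, seed=11)


@pytest.fixture(scope="session")
def space_phantom():
    return generate_space_phantom(SpacePhantomSpec(), seed=5)


@pytest.fixture(scope="session")
def fiducial_section():
    """300 nm blank section with 20 beads per surface, margins safe at 45 deg."""
    vol = generate_blank_resin((100, 160, 160), (3.0, 3.0, 3.0),
                               noise_gaussian_sd=0.0, seed=1)
    vol_b, beads = add_fiducials(vol, 20, seed=2, margin_nm=110.0)
    return vol_b, beads


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
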