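"""Shared fixtures: full helmet geometry plus desk-scale systems.

The desk-scale fixtures shrink the MCE count, the detector pixelation and
the grid so that system matrices build in seconds while keeping the full
physics (tungsten ray marching, DOI layers, solid angles).
"""

import numpy as np
import pytest

from helmetspect.apertures import aperture_defaults
from helmetspect.geometry import DetectorSpec, build_helmet
from helmetspect.io import subsample_helmet
from helmetspect.system_matrix import SRMOptions, VolumeGrid, build_srm


@pytest.fixture(scope="session")
def helmet():
    return build_helmet()


@pytest.fixture(scope="session")
def det_full():
    return DetectorSpec()


@pytest.fixture(scope="session")
def det_small():
    """16 x 16 pixels of 1.25 mm pitch on the same 20-mm module."""
    return DetectorSpec(n_pix_u=16, n_pix_v=16, pitch=1.25)


@pytest.fixture(scope="session")
def tiny_system(helmet, det_small):
    """24-MCE helmet, 16^2-pixel modules, 15^3 x 12-mm grid (odd size, so
    one voxel centre sits exactly at the FOV centre), ring apertures: a
    complete system whose SRM builds in a few seconds."""
    geometry = subsample_helmet(helmet, 24)
    grid = VolumeGrid(shape=(15, 15, 15), voxel_size=12.0)
    aperture = aperture_defaults("ring_250")
    options = SRMOptions(trans_floor=1e-4)
    srm = build_srm(geometry, det_small, aperture, grid, options)
    return {
        "geometry": geometry,
        "det": det_small,
        "grid": grid,
        "aperture": aperture,
        "options": options,
        "srm": srm,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210712)
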