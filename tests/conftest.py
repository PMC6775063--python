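"""Shared fixtures: synthetic bead fields, scan specs and simulators."""

import numpy as np
import pytest
from skimage import transform as sktransform

from sheetscan import scan, synth


def make_bead_field(
    seed,
    sigma=2.0,
    shape=(128, 96),
    n=40,
    amplitude=400.0,
    background=10.0,
    min_sep=10.0,
):
    """Sparse 2-D Gaussian bead field, band-limited for warp fidelity."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        p = rng.random(2) * [shape[0] - 12, shape[1] - 12] + 6
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    img = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for y, x in pts:
        img += amplitude * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return img, np.array(pts)


def random_stitch_transform(rng):
    """Small rigid+anisotropic-scale misalignment, magnitudes as calibrated
    two-camera systems show (sub-degree rotation, ~0.5% scale, few px)."""
    theta = np.deg2rad(rng.uniform(-0.3, 0.3))
    scale = 1 + rng.uniform(-0.005, 0.005, 2)
    trans = rng.uniform(-2, 2, 2)
    return sktransform.AffineTransform(
        matrix=sktransform.AffineTransform(scale=scale).params
        @ sktransform.EuclideanTransform(rotation=theta, translation=trans).params
    )


@pytest.fixture
def bead_field():
    return make_bead_field


@pytest.fixture
def scan_spec_200():
    return scan.ScanSpec(
        z_min=0.0, z_max=200.0, cycle_frequency=10.0, sample_rate=10000.0, slice_spacing=5.0
    )


@pytest.fixture
def scan_spec_700():
    return scan.ScanSpec(
        z_min=0.0, z_max=700.0, cycle_frequency=20.0, sample_rate=10000.0, slice_spacing=5.0
    )


@pytest.fixture
def plant():
    return synth.PlantModel()


@pytest.fixture
def unity_plant():
    """Plant that returns the command unchanged (perfect tracking)."""

    def run(command):
        return command

    return run
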