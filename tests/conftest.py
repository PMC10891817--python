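"""Shared fixtures: small deterministic phantoms and random generators."""

import numpy as np
import pytest

from markreg import (
    CardiacPhantomSpec,
    JawPhantomSpec,
    LandmarkPairing,
    LandmarkSet,
    RigidTransform,
    Volume,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240207)


@pytest.fixture
def unit_volume():
    """100^3 volume, 1 mm spacing, origin 0, identity direction."""
    data = np.zeros((100, 100, 100), dtype=np.float32)
    return Volume(data=data, spacing=(1, 1, 1), origin=(0, 0, 0))


@pytest.fixture
def smooth_volume(rng):
    """Smooth random volume (band-limited) for interpolation tests."""
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.normal(size=(40, 36, 30)), sigma=3).astype(np.float64)
    return Volume(data=data, spacing=(0.8, 1.0, 1.2), origin=(-5.0, 3.0, -7.0))


@pytest.fixture
def small_cardiac_spec():
    """Reduced grids, clean, identity pose: fast deterministic scene."""
    return CardiacPhantomSpec(
        ct_shape=(64, 64, 32),
        us_shape=(48, 48, 64),
        noise_sd=0.0,
        true_transform=RigidTransform.identity(),
        seed=11,
    )


@pytest.fixture
def jaw_spec():
    return JawPhantomSpec(seed=5)


def random_rigid(rng, max_translation=100.0):
    """Uniform random rotation (QR of a Gaussian matrix) + bounded translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(q, t)


def random_pairing(rng, n, transform, sigma=0.0):
    """Moving points + their (optionally noisy) transformed fixed partners."""
    moving = LandmarkSet(rng.uniform(-50, 50, size=(n, 3)))
    fixed_pts = transform.apply(moving.points)
    if sigma > 0:
        fixed_pts = fixed_pts + rng.normal(0, sigma, size=(n, 3))
    fixed = LandmarkSet(fixed_pts, list(moving.labels))
    return LandmarkPairing(fixed, moving)
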