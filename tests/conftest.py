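"""Shared fixtures: small phantoms and their correlation matrices.

The "tiny" phantom trades realism for speed: 4 segments at 1 μm pitch with
a small cross-section, keeping every registration matrix in the suite a
few hundred pairs.  Geometry (period, asymmetric dispersion, enrichment)
follows the wild-type architecture.
"""

from __future__ import annotations

import numpy as np
import pytest

from vncorr import (
    PhantomParams,
    bin_and_project,
    generate_phantom,
    self_correlation_matrix,
)

TINY = dict(
    n_segments=4,
    period=26.0,
    min_offset=8.0,
    voxel_pitch=1.0,
    cross_section=(28, 16),
    dispersion_amp=3.4,
    node_halfwidth=1.5,
    psf_sigma=0.4,
)


@pytest.fixture(scope="session")
def tiny_params() -> PhantomParams:
    return PhantomParams(noise_gaussian_sd=0.02, seed=7, **TINY)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_params):
    return generate_phantom(tiny_params)


@pytest.fixture(scope="session")
def noiseless_params() -> PhantomParams:
    return PhantomParams(noise_gaussian_sd=0.0, seed=7, **TINY)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_params):
    return generate_phantom(noiseless_params)


@pytest.fixture(scope="session")
def tiny_slabs(tiny_phantom):
    stack, _ = tiny_phantom
    return bin_and_project(stack, bin_length=1.65)  # realizes 2.0 μm bins


@pytest.fixture(scope="session")
def tiny_matrix(tiny_slabs):
    return self_correlation_matrix(tiny_slabs)


def make_blobs(seed: int = 0, shape: tuple[int, int] = (40, 40), n: int = 6) -> np.ndarray:
    """A smooth multi-blob test section (positive, non-degenerate)."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    yy, xx = np.indices(shape)
    for _ in range(n):
        cy = rng.uniform(0.2 * shape[0], 0.8 * shape[0])
        cx = rng.uniform(0.2 * shape[1], 0.8 * shape[1])
        img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.5**2))
    return img


@pytest.fixture
def blobs():
    return make_blobs
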