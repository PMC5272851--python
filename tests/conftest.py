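"""Shared fixtures: small, fast synthetic studies reused across the suite."""

import numpy as np
import pytest

from spectsbr import CameraModel, PhantomSpec, build_phantom, simulate_scan


@pytest.fixture(scope="session")
def desk_spec():
    """10:1 phantom geometry on the coarse 64x64x32, 4 mm grid."""
    return PhantomSpec(filling_ratio=10.0).desk_scale()


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    return build_phantom(desk_spec)


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest representable geometry (32x32x16, 8 mm) for pipeline smoke."""
    return PhantomSpec(filling_ratio=10.0, matrix=(32, 32, 16), voxel_size_mm=8.0)


@pytest.fixture(scope="session")
def clean_camera():
    """Blur-free, contamination-free camera: isolates geometry and algebra."""
    return CameraModel(
        name="clean",
        psf_fwhm_mm=0.0,
        scatter_fraction_lower=0.0,
        septal_penetration_fraction=0.0,
    )


@pytest.fixture(scope="session")
def default_camera():
    return CameraModel(name="default", psf_fwhm_mm=10.0, seed=11)


@pytest.fixture(scope="session")
def clean_scan(desk_phantom, clean_camera):
    """Noiseless, attenuation-free, contamination-free projections."""
    return simulate_scan(
        desk_phantom, clean_camera, attenuation=False, noise=False
    )


@pytest.fixture(scope="session")
def realistic_scan(desk_phantom, default_camera):
    """Noisy scan with attenuation, scatter and septal penetration."""
    return simulate_scan(desk_phantom, default_camera, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
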