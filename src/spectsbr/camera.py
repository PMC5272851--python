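"""Gamma-camera model.

A camera is described by the handful of parameters that matter for
parallel-collimator brain SPECT at the level of this package: the number of
projection angles, detector pixel size, an effective in-plane resolution
(Gaussian PSF FWHM), a global sensitivity, and two dimensionless
contamination fractions.  ``scatter_fraction_lower`` is the Compton-scatter
contamination reaching the photopeak window, expressed relative to primary
counts; ``septal_penetration_fraction`` is the analogous high-energy septal
penetration term, which dominates the upper satellite window for 123-I.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_N_PROJECTIONS = (120, 128)


@dataclass(frozen=True)
class CameraModel:
    """Parallel-collimator SPECT camera description.

    Parameters
    ----------
    name
        Identifier used in provenance and calibration tables.
    n_projections
        Number of projection angles over 360 degrees; 120 or 128
        (the two acquisition conventions supported downstream, which also
        select the default OSEM iteration/subset scheme).
    pixel_size_mm
        Detector bin size (isotropic), millimetres.
    psf_fwhm_mm
        In-plane Gaussian blur FWHM modelling collimator/detector
        resolution at the fixed standard orbit radius.
    sensitivity
        Counts per unit activity per projection (arbitrary scale; ratios
        are what matter downstream).
    scatter_fraction_lower
        Photopeak scatter contamination as a fraction of primary counts.
    septal_penetration_fraction
        Photopeak septal-penetration contamination as a fraction of
        primary counts.
    seed
        Default RNG seed for scans simulated with this camera.
    """

    name: str = "generic"
    n_projections: int = 120
    pixel_size_mm: float = 4.0
    psf_fwhm_mm: float = 10.0
    sensitivity: float = 1.0
    scatter_fraction_lower: float = 0.45
    septal_penetration_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_projections not in VALID_N_PROJECTIONS:
            raise ValueError(
                f"n_projections must be one of {VALID_N_PROJECTIONS}, "
                f"got {self.n_projections}"
            )
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        for attr in ("scatter_fraction_lower", "septal_penetration_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{attr} must be in [0, 1), got {v}")

    @property
    def angles_deg(self) -> "tuple[float, ...]":
        """Evenly spaced projection angles over a full 360-degree orbit."""
        step = 360.0 / self.n_projections
        return tuple(i * step for i in range(self.n_projections))

    def default_osem_scheme(self) -> "tuple[int, int]":
        """(iterations, subsets) convention tied to the angle count."""
        return (10, 10) if self.n_projections == 120 else (8, 12)


def default_camera_pool(n: int = 9, seed: int = 0) -> "list[CameraModel]":
    """A pool of cameras with varied resolution and collimation.

    PSF FWHM spans 8-16 mm and the penetration fraction varies, emulating
    the spread in collimation performance between manufacturers.
    """
    cameras = []
    for i in range(n):
        frac = i / max(n - 1, 1)
        cameras.append(
            CameraModel(
                name=f"camera{i:02d}",
                n_projections=120 if i % 3 else 128,
                psf_fwhm_mm=8.0 + 8.0 * frac,
                sensitivity=1.0 + 0.3 * ((i * 7) % 5) / 4.0,
                scatter_fraction_lower=0.40 + 0.10 * frac,
                septal_penetration_fraction=0.18 + 0.14 * ((i * 3) % n) / max(n - 1, 1),
                seed=seed + i,
            )
        )
    return cameras
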