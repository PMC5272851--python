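"""Scan simulation: triple-energy-window projection data with Poisson noise.

Energy windows are not simulated physically.  Instead the window contents
are generated from parametric spatial kernels applied to the primary
(attenuated, PSF-blurred) projections:

* Compton scatter: a wide Gaussian kernel (FWHM 60 mm) scaled by the
  camera's scatter fraction.  Mostly below the photopeak, so it is weighted
  towards the lower satellite window.
* Septal penetration of the 123-I high-energy emissions: a very wide
  kernel (FWHM 150 mm) plus a flat floor, weighted towards the upper
  satellite window.
* Extra-brain activity (human scans only): a spatially broad count floor
  with a caudal gradient, strongest in the upper window — the chest and
  abdomen sources contribute chiefly through septal penetration.

The satellite-window weights of each component sum to 2, so the
triple-energy-window estimate ``(sc_l + sc_u)/(2 w_sc) * w_ph`` equals the
photopeak contamination in expectation; the correction is unbiased for the
model, and residual errors come from Poisson noise and the estimate
smoothing, as in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .camera import CameraModel
from .phantoms import (
    OUTSIDE,
    ActivityVolume,
    PhantomSpec,
    SubjectSpec,
    build_phantom,
    build_subject,
)
from .projector import forward_project

MU_WATER_CM = 0.143  # uniform tissue attenuation coefficient, cm^-1

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SCATTER_KERNEL_FWHM_MM = 60.0
PENETRATION_KERNEL_FWHM_MM = 150.0
PENETRATION_FLAT_WEIGHT = 0.2
# satellite-window weights (per component, lower/upper); each pair sums to 2
SCATTER_WINDOW_WEIGHTS = (1.7, 0.3)
PENETRATION_WINDOW_WEIGHTS = (0.6, 1.4)
EXTRA_BRAIN_WINDOW_WEIGHTS = (0.3, 1.7)

DEFAULT_TOTAL_PH_COUNTS = 2_000_000


@dataclass
class ProjectionSet:
    """Multi-angle projections in photopeak and two satellite windows.

    ``ph``, ``sc_l``, ``sc_u`` have shape (n_projections, nu, nv); window
    widths are in keV (photopeak 159 keV +/- 10% by default).  ``meta``
    carries camera name, ground truth and simulation provenance.
    """

    ph: np.ndarray
    sc_l: np.ndarray
    sc_u: np.ndarray
    angles: np.ndarray
    w_ph: float = 32.0
    w_sc: float = 7.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("ph", "sc_l", "sc_u"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative counts")
            setattr(self, name, arr)
        if not (self.ph.shape == self.sc_l.shape == self.sc_u.shape):
            raise ValueError("window arrays must share one shape")
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) != self.ph.shape[0]:
            raise ValueError("number of angles must match projections")
        if self.w_ph <= 0 or self.w_sc <= 0:
            raise ValueError("window widths must be positive")


def _broad_blur(projections: np.ndarray, fwhm_mm: float, pixel_mm: float):
    sigma = fwhm_mm * _FWHM_TO_SIGMA / pixel_mm
    return ndimage.gaussian_filter(projections, sigma=(0, sigma, sigma))


def _extra_brain_shape(shape) -> np.ndarray:
    """Unit-total broad floor with a caudal (inferior) gradient."""
    n_ang, nu, nv = shape
    v = np.arange(nv)
    profile = 1.0 + (1.0 - v / max(nv - 1, 1))  # 2 at the caudal edge, 1 at vertex
    e = np.ones((n_ang, nu, nv)) * profile[None, None, :]
    return e / e.sum()


def head_mu_map(vol: ActivityVolume, mu: float = MU_WATER_CM) -> np.ndarray:
    """Uniform attenuation map over the head (non-outside labels)."""
    return np.where(vol.labels != OUTSIDE, mu, 0.0)


def simulate_scan(
    vol: ActivityVolume,
    camera: CameraModel | None = None,
    subject: SubjectSpec | None = None,
    total_ph_counts: float = DEFAULT_TOTAL_PH_COUNTS,
    seed: int | None = None,
    attenuation: bool = True,
    noise: bool = True,
    w_ph: float = 32.0,
    w_sc: float = 7.0,
) -> ProjectionSet:
    """Simulate one triple-energy-window SPECT acquisition.

    The photopeak expectation (primary + scatter + septal penetration +
    extra-brain floor) is normalised to ``total_ph_counts`` and all three
    windows are Poisson-sampled unless ``noise=False``.
    """
    if total_ph_counts <= 0:
        raise ValueError("total_ph_counts must be positive")
    camera = camera or CameraModel()
    mu = head_mu_map(vol) if attenuation else None
    primary = forward_project(vol, mu, camera)

    pix = vol.voxel_size_mm
    f_sc = camera.scatter_fraction_lower
    f_sp = camera.septal_penetration_fraction
    e_frac = subject.extra_brain_fraction if subject is not None else 0.0

    scatter = f_sc * _broad_blur(primary, SCATTER_KERNEL_FWHM_MM, pix)
    broad = _broad_blur(primary, PENETRATION_KERNEL_FWHM_MM, pix)
    flat = np.full_like(primary, primary.mean())
    penetration = f_sp * (
        (1.0 - PENETRATION_FLAT_WEIGHT) * broad + PENETRATION_FLAT_WEIGHT * flat
    )
    extra = e_frac * primary.sum() * _extra_brain_shape(primary.shape)

    ph = primary + scatter + penetration + extra
    wl_sc, wu_sc = SCATTER_WINDOW_WEIGHTS
    wl_sp, wu_sp = PENETRATION_WINDOW_WEIGHTS
    wl_eb, wu_eb = EXTRA_BRAIN_WINDOW_WEIGHTS
    ratio = w_sc / w_ph
    sc_l = ratio * (wl_sc * scatter + wl_sp * penetration + wl_eb * extra)
    sc_u = ratio * (wu_sc * scatter + wu_sp * penetration + wu_eb * extra)

    scale = total_ph_counts / ph.sum()
    ph, sc_l, sc_u = ph * scale, sc_l * scale, sc_u * scale

    if noise:
        rng = np.random.default_rng(camera.seed if seed is None else seed)
        ph = rng.poisson(ph).astype(np.float64)
        sc_l = rng.poisson(sc_l).astype(np.float64)
        sc_u = rng.poisson(sc_u).astype(np.float64)

    true_l, true_r = vol.true_sbr_sides()
    meta = {
        "camera": camera.name,
        "n_projections": camera.n_projections,
        "true_sbr_left": true_l,
        "true_sbr_right": true_r,
        "extra_brain_fraction": e_frac,
        "attenuation": attenuation,
        "noise": noise,
        "total_ph_counts": total_ph_counts,
        "voxel_size_mm": vol.voxel_size_mm,
    }
    if subject is not None:
        meta.update(
            subject_id=subject.subject_id,
            age=subject.age,
            sex=subject.sex,
            study_type="human",
        )
    return ProjectionSet(
        ph, sc_l, sc_u, np.asarray(camera.angles_deg), w_ph, w_sc, meta
    )


def generate_phantom_series(
    camera: CameraModel,
    ratios=(10.0, 8.0, 5.0, 4.0, 1.0),
    seed: int = 0,
    geometry: PhantomSpec | None = None,
    total_ph_counts: float = DEFAULT_TOTAL_PH_COUNTS,
    noise: bool = True,
):
    """One phantom scan per filling ratio on a single camera.

    Phantom scans carry no extra-brain contamination; the returned list of
    ``(PhantomSpec, ProjectionSet)`` is the input to calibration fitting.
    """
    geometry = geometry or PhantomSpec()
    if any(r < 1 for r in ratios):
        raise ValueError("filling ratios must be >= 1")
    out = []
    for i, ratio in enumerate(ratios):
        spec = PhantomSpec(
            filling_ratio=float(ratio),
            striatal_volume_ml=geometry.striatal_volume_ml,
            head_axes_mm=geometry.head_axes_mm,
            matrix=geometry.matrix,
            voxel_size_mm=geometry.voxel_size_mm,
            rim_thickness_mm=geometry.rim_thickness_mm,
        )
        vol = build_phantom(spec)
        scan = simulate_scan(
            vol,
            camera,
            subject=None,
            total_ph_counts=total_ph_counts,
            seed=seed + i,
            noise=noise,
        )
        scan.meta["filling_ratio"] = float(ratio)
        scan.meta["study_type"] = "phantom"
        scan.meta["subject_id"] = f"phantom_{camera.name}_r{ratio:g}"
        out.append((spec, scan))
    return out


def draw_cohort_specs(
    n_subjects: int,
    decline: float = -0.055,
    intercept: float = 12.0,
    sd_biological: float = 1.0,
    seed: int = 0,
    extra_brain_fraction: float = 0.3,
) -> "list[SubjectSpec]":
    """Draw the ground truth for a gender-balanced healthy-control cohort.

    Ages are uniform on [30, 90]; true SBR follows a linear age decline
    plus Gaussian biological spread, truncated at zero; sexes alternate so
    counts differ by at most one.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if decline > 0:
        raise ValueError("decline must be <= 0 (SBR falls with age)")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(30.0, 90.0, size=n_subjects)
    sbr = intercept + decline * ages + rng.normal(0.0, sd_biological, n_subjects)
    sbr = np.clip(sbr, 0.0, None)
    return [
        SubjectSpec(
            subject_id=f"sub{i:04d}",
            age=float(ages[i]),
            sex="F" if i % 2 == 0 else "M",
            true_sbr_left=float(sbr[i]),
            true_sbr_right=float(sbr[i]),
            extra_brain_fraction=extra_brain_fraction,
        )
        for i in range(n_subjects)
    ]


def generate_cohort(
    n_subjects: int,
    decline: float = -0.055,
    intercept: float = 12.0,
    sd_biological: float = 1.0,
    camera_pool=None,
    seed: int = 0,
    geometry: PhantomSpec | None = None,
    extra_brain_fraction: float = 0.3,
    total_ph_counts: float = DEFAULT_TOTAL_PH_COUNTS,
    noise: bool = True,
):
    """Simulate a healthy-control cohort; see :func:`draw_cohort_specs`.

    Subjects rotate round-robin through the camera pool.  Returns a list
    of ``(SubjectSpec, ProjectionSet)``, fully reproducible from the seed.
    """
    camera_pool = list(camera_pool) if camera_pool else [CameraModel()]
    geometry = geometry or PhantomSpec()
    subjects = draw_cohort_specs(
        n_subjects, decline, intercept, sd_biological, seed, extra_brain_fraction
    )
    rng = np.random.default_rng(seed)
    scan_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)

    out = []
    for i, subject in enumerate(subjects):
        vol = build_subject(subject, geometry)
        camera = camera_pool[i % len(camera_pool)]
        scan = simulate_scan(
            vol,
            camera,
            subject=subject,
            total_ph_counts=total_ph_counts,
            seed=int(scan_seeds[i]),
            noise=noise,
        )
        out.append((subject, scan))
    return out
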