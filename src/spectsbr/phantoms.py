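"""Digital striatal phantoms and human-like head models.

The anthropomorphic striatal phantom is modelled as an ellipsoidal head
shell containing a uniform background compartment and two striata, each a
caudate + putamen ellipsoid pair, filled at a known striatum:background
concentration ratio (the *filling ratio*).  By construction the true
specific binding ratio is ``filling_ratio - 1``.

Human-like models reuse the same geometry but set per-side striatal
concentrations from ground-truth SBRs, optionally carving out a
zero-activity ventricular space.  Extra-brain activity (lungs, liver, ...)
is *not* part of the head volume; it is attached at projection level by the
scan simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

# Compartment label codes shared across the package.
OUTSIDE = 0
BACKGROUND = 1
CAUDATE_L = 2
CAUDATE_R = 3
PUTAMEN_L = 4
PUTAMEN_R = 5
OCCIPITAL = 6
RIM = 7

STRIATAL_LABELS_L = (CAUDATE_L, PUTAMEN_L)
STRIATAL_LABELS_R = (CAUDATE_R, PUTAMEN_R)
STRIATAL_LABELS = STRIATAL_LABELS_L + STRIATAL_LABELS_R

# Base sub-striatal ellipsoids in head-centred mm coordinates
# (x: left->right positive left, y: posterior->anterior, z: inferior->superior).
# Semi-axes are rescaled at build time so the discretised per-side volume
# matches the requested striatal volume.
_CAUDATE_CENTER = (16.0, 20.0, 4.0)
_CAUDATE_AXES = (7.0, 14.0, 10.0)
_PUTAMEN_CENTER = (28.0, 2.0, 0.0)
_PUTAMEN_AXES = (9.0, 16.0, 11.0)

_OCCIPITAL_CENTER = (0.0, -62.0, 2.0)
_OCCIPITAL_AXES = (40.0, 24.0, 26.0)

_VENTRICLE_CENTER = (9.0, 10.0, 10.0)
_VENTRICLE_AXES = (5.0, 16.0, 7.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and filling of a digital striatal phantom.

    ``filling_ratio`` is the striatum:background activity concentration
    ratio (>= 1); the true SBR is ``filling_ratio - 1``.  ``head_axes_mm``
    are the semi-axes of the head shell ellipsoid.
    """

    filling_ratio: float = 10.0
    striatal_volume_ml: float = 11.4
    head_axes_mm: "tuple[float, float, float]" = (70.0, 95.0, 55.0)
    matrix: "tuple[int, int, int]" = (128, 128, 64)
    voxel_size_mm: float = 2.0
    rim_thickness_mm: float = 10.0
    ventricle_void: bool = False

    def __post_init__(self) -> None:
        if self.filling_ratio < 1:
            raise ValueError("filling_ratio must be >= 1")
        if self.striatal_volume_ml <= 0:
            raise ValueError("striatal_volume_ml must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        half_extent = [m * self.voxel_size_mm / 2.0 for m in self.matrix]
        if any(a >= h for a, h in zip(self.head_axes_mm, half_extent)):
            raise ValueError(
                "matrix too small to contain head_axes_mm at this voxel size"
            )

    @property
    def true_sbr(self) -> float:
        return self.filling_ratio - 1.0

    def desk_scale(self) -> "PhantomSpec":
        """Same physical geometry on a coarser 64x64x32, 4 mm grid."""
        return replace(self, matrix=(64, 64, 32), voxel_size_mm=4.0)


@dataclass(frozen=True)
class SubjectSpec:
    """Ground truth for one simulated healthy control.

    ``extra_brain_fraction`` is the count contribution from activity
    outside the head (scatter and septal penetration from chest/abdomen),
    expressed as a fraction of primary photopeak counts.  Phantom scans
    have it equal to zero.
    """

    subject_id: str
    age: float
    sex: str
    true_sbr_left: float
    true_sbr_right: float
    extra_brain_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 30.0 <= self.age <= 90.0:
            raise ValueError("age must be within the 30-90 year cohort range")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.true_sbr_left < 0 or self.true_sbr_right < 0:
            raise ValueError("true SBRs must be non-negative")
        if self.extra_brain_fraction < 0:
            raise ValueError("extra_brain_fraction must be non-negative")


@dataclass
class ActivityVolume:
    """Voxelised activity map with its compartment label map."""

    activity: np.ndarray
    labels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.activity.shape != self.labels.shape:
            raise ValueError("activity and labels must share one grid")
        if np.any(self.activity < 0):
            raise ValueError("activity must be non-negative")
        if np.any(self.activity[self.labels == OUTSIDE] != 0):
            raise ValueError("activity must vanish outside the head")

    @property
    def shape(self) -> "tuple[int, ...]":
        return self.activity.shape

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3

    def label_mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels, codes)

    def label_mean(self, *codes: int) -> float:
        mask = self.label_mask(*codes)
        if not mask.any():
            raise ValueError(f"no voxels carry labels {codes}")
        return float(self.activity[mask].mean())

    def background_concentration(self) -> float:
        """Mean over non-void background voxels (ventricles excluded)."""
        mask = self.label_mask(BACKGROUND, OCCIPITAL, RIM) & (self.activity > 0)
        return float(self.activity[mask].mean())

    def true_sbr_sides(self) -> "tuple[float, float]":
        """(left, right) striatal/background concentration ratio minus 1."""
        bg = self.background_concentration()
        left = self.label_mean(*STRIATAL_LABELS_L) / bg - 1.0
        right = self.label_mean(*STRIATAL_LABELS_R) / bg - 1.0
        return left, right

    def striatal_volume_ml_sides(self) -> "tuple[float, float]":
        v = self.voxel_volume_ml
        return (
            float(self.label_mask(*STRIATAL_LABELS_L).sum()) * v,
            float(self.label_mask(*STRIATAL_LABELS_R).sum()) * v,
        )


def _grid_mm(matrix, voxel_size_mm):
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel_size_mm for n in matrix]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(X, Y, Z, center, axes):
    return (
        ((X - center[0]) / axes[0]) ** 2
        + ((Y - center[1]) / axes[1]) ** 2
        + ((Z - center[2]) / axes[2]) ** 2
    ) <= 1.0


def _side_masks(X, Y, Z, scale: float, side: int):
    """Caudate and putamen masks for one side (+1 left, -1 right)."""
    cc = (side * _CAUDATE_CENTER[0], _CAUDATE_CENTER[1], _CAUDATE_CENTER[2])
    pc = (side * _PUTAMEN_CENTER[0], _PUTAMEN_CENTER[1], _PUTAMEN_CENTER[2])
    ca = tuple(a * scale for a in _CAUDATE_AXES)
    pa = tuple(a * scale for a in _PUTAMEN_AXES)
    caud = _ellipsoid(X, Y, Z, cc, ca)
    puta = _ellipsoid(X, Y, Z, pc, pa) & ~caud
    return caud, puta


def _fit_striatal_scale(X, Y, Z, voxel_volume_ml: float, target_ml: float) -> float:
    """Scale factor on the sub-striatal semi-axes matching the target volume.

    Bisection on the discretised per-side voxel count; the mask volume is a
    step function of the scale, so the result is within one voxel of the
    achievable optimum.
    """

    def vol(scale):
        caud, puta = _side_masks(X, Y, Z, scale, side=+1)
        return (int(caud.sum()) + int(puta.sum())) * voxel_volume_ml

    lo, hi = 0.5, 1.6
    if vol(lo) > target_ml or vol(hi) < target_ml:
        raise ValueError("striatal volume unrepresentable within geometry bounds")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if vol(mid) < target_ml:
            lo = mid
        else:
            hi = mid
    # pick the endpoint with the smaller volume error
    return lo if abs(vol(lo) - target_ml) <= abs(vol(hi) - target_ml) else hi


_LABELS_CACHE: "dict[PhantomSpec, np.ndarray]" = {}


def build_labels(spec: PhantomSpec) -> np.ndarray:
    """Compartment label map for the phantom/head geometry.

    The map depends only on the geometry fields, so results are cached per
    spec (cohort generation reuses one geometry across many subjects).
    """
    key = replace(spec, filling_ratio=1.0)
    if key in _LABELS_CACHE:
        return _LABELS_CACHE[key].copy()
    X, Y, Z = _grid_mm(spec.matrix, spec.voxel_size_mm)
    head = _ellipsoid(X, Y, Z, (0.0, 0.0, 0.0), spec.head_axes_mm)

    labels = np.zeros(spec.matrix, dtype=np.int16)
    labels[head] = BACKGROUND

    # outer rim: shell of given physical thickness inside the head boundary
    depth = ndimage.distance_transform_edt(
        head, sampling=[spec.voxel_size_mm] * 3
    )
    rim = head & (depth <= spec.rim_thickness_mm)
    labels[rim] = RIM

    occ = _ellipsoid(X, Y, Z, _OCCIPITAL_CENTER, _OCCIPITAL_AXES) & head & ~rim
    labels[occ] = OCCIPITAL

    scale = _fit_striatal_scale(
        X, Y, Z, (spec.voxel_size_mm / 10.0) ** 3, spec.striatal_volume_ml
    )
    for side, (cl, pl) in ((+1, (CAUDATE_L, PUTAMEN_L)), (-1, (CAUDATE_R, PUTAMEN_R))):
        caud, puta = _side_masks(X, Y, Z, scale, side)
        labels[caud & head] = cl
        labels[puta & head] = pl

    n_side = int(np.isin(labels, STRIATAL_LABELS_L).sum())
    if n_side < 20:
        raise ValueError(
            f"striatal volume unrepresentable on this grid "
            f"({n_side} voxels/striatum; need >= 20)"
        )
    _LABELS_CACHE[key] = labels
    return labels.copy()


def _ventricle_mask(spec: PhantomSpec) -> np.ndarray:
    X, Y, Z = _grid_mm(spec.matrix, spec.voxel_size_mm)
    left = _ellipsoid(X, Y, Z, _VENTRICLE_CENTER, _VENTRICLE_AXES)
    rc = (-_VENTRICLE_CENTER[0], _VENTRICLE_CENTER[1], _VENTRICLE_CENTER[2])
    return left | _ellipsoid(X, Y, Z, rc, _VENTRICLE_AXES)


def build_phantom(spec: PhantomSpec) -> ActivityVolume:
    """Striatal phantom at a known filling ratio.

    Background compartment at unit concentration, both striata at
    ``filling_ratio`` times that, no extra-brain activity.
    """
    labels = build_labels(spec)
    activity = np.zeros(spec.matrix, dtype=np.float64)
    activity[labels != OUTSIDE] = 1.0
    activity[np.isin(labels, STRIATAL_LABELS)] = spec.filling_ratio
    if spec.ventricle_void:
        vent = _ventricle_mask(spec) & (labels == BACKGROUND)
        activity[vent] = 0.0
    return ActivityVolume(activity, labels, spec.voxel_size_mm)


def build_subject(
    subject: SubjectSpec, geometry: PhantomSpec | None = None
) -> ActivityVolume:
    """Human-like head model with per-side ground-truth SBRs.

    Striatal concentration on each side is ``(1 + true_sbr) x background``;
    the subject's extra-brain contamination is added later at projection
    level by the scan simulator, never into the head volume.
    """
    geometry = geometry or PhantomSpec()
    labels = build_labels(geometry)
    activity = np.zeros(geometry.matrix, dtype=np.float64)
    activity[labels != OUTSIDE] = 1.0
    activity[np.isin(labels, STRIATAL_LABELS_L)] = 1.0 + subject.true_sbr_left
    activity[np.isin(labels, STRIATAL_LABELS_R)] = 1.0 + subject.true_sbr_right
    if geometry.ventricle_void:
        vent = _ventricle_mask(geometry) & (labels == BACKGROUND)
        activity[vent] = 0.0
    return ActivityVolume(activity, labels, geometry.voxel_size_mm)
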