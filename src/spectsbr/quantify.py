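"""Striatal specific binding ratio quantification.

Two estimators of SBR = c_s / c_ns are provided:

* **BRASS-style**: count concentration inside tight anatomical VOIs
  (caudate + putamen per side, pooled over their combined volume) with the
  occipital cortex as the non-specific reference.  The small VOIs make it
  susceptible to partial-volume losses.
* **Southampton (SUSI)**: total counts inside a generous geometric VOI
  that captures all striatal counts including those blurred beyond the
  anatomical boundary; the non-specific background (mean over the whole
  brain minus the striatal VOIs and an outer rim) times the VOI volume is
  subtracted, and the specific counts are converted to a concentration via
  an assumed striatal volume (11.4 ml).  This averts partial-volume
  losses by construction.

Template registration is out of scope: VOIs are placed from the known
synthetic geometry, optionally re-centred on the count centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantoms import (
    CAUDATE_L,
    CAUDATE_R,
    OCCIPITAL,
    OUTSIDE,
    PUTAMEN_L,
    PUTAMEN_R,
    RIM,
    STRIATAL_LABELS_L,
    STRIATAL_LABELS_R,
    ActivityVolume,
    PhantomSpec,
    build_labels,
)

QUANT_METHODS = ("brass", "southampton")


class QuantificationError(ValueError):
    """Raised when a non-specific reference concentration is unusable."""


@dataclass(frozen=True)
class QuantConfig:
    striatal_volume_ml: float = 11.4  # assumed per-striatum volume (SUSI)
    rim_thickness_mm: float = 10.0
    southampton_margin_mm: float = 12.0
    registration: str = "identity"  # or "centroid"

    def __post_init__(self) -> None:
        if self.striatal_volume_ml <= 0:
            raise ValueError("striatal_volume_ml must be positive")
        if self.registration not in ("identity", "centroid"):
            raise ValueError("registration must be 'identity' or 'centroid'")


@dataclass
class SBRRecord:
    subject_id: str
    side: str  # "L" | "R"
    method: str  # "brass" | "southampton"
    recon: str  # "FBP" | "IRNC" | "IRAC" | "ACSC"
    camera: str
    sbr: float
    c_s: float
    c_ns: float
    calibrated: bool = False
    sbr_uncalibrated: float | None = None
    age: float | None = None
    sex: str | None = None
    true_sbr: float | None = None


@dataclass
class VOISet:
    """Anatomical and Southampton volume-of-interest masks on one grid."""

    anatomical: "dict[str, np.ndarray]"
    southampton_striatal: "dict[str, np.ndarray]"  # keys "L", "R"
    southampton_reference: np.ndarray
    voxel_size_mm: float

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3


def _volume_data(volume) -> np.ndarray:
    if isinstance(volume, ActivityVolume):
        return volume.activity
    data = getattr(volume, "data", volume)
    return np.asarray(data, dtype=np.float64)


def place_vois(volume, geometry: PhantomSpec, cfg: QuantConfig | None = None) -> VOISet:
    """Build both VOI schemes from the known synthetic geometry.

    The Southampton striatal VOI on each side is the anatomical striatum
    dilated by a physical margin (clipped at the midline so the two sides
    stay disjoint); the reference is the brain minus both striatal VOIs
    and minus the outer rim.
    """
    cfg = cfg or QuantConfig()
    data = _volume_data(volume)
    if cfg.rim_thickness_mm != geometry.rim_thickness_mm:
        geometry = replace(geometry, rim_thickness_mm=cfg.rim_thickness_mm)
    labels = build_labels(geometry)
    if labels.shape != data.shape:
        raise ValueError(
            f"geometry grid {labels.shape} does not match volume grid {data.shape}"
        )

    if cfg.registration == "centroid":
        com_data = np.array(ndimage.center_of_mass(np.clip(data, 0, None)))
        com_labels = np.array(ndimage.center_of_mass(labels != OUTSIDE))
        shift = np.round(com_data - com_labels).astype(int)
        labels = np.roll(labels, shift, axis=(0, 1, 2))

    anatomical = {
        "caudate_L": labels == CAUDATE_L,
        "caudate_R": labels == CAUDATE_R,
        "putamen_L": labels == PUTAMEN_L,
        "putamen_R": labels == PUTAMEN_R,
        "occipital": labels == OCCIPITAL,
    }

    nx = labels.shape[0]
    x_mm = (np.arange(nx) - (nx - 1) / 2.0)[:, None, None] * geometry.voxel_size_mm
    sampling = [geometry.voxel_size_mm] * 3
    striatal_boxes = {}
    for side, lab in (("L", STRIATAL_LABELS_L), ("R", STRIATAL_LABELS_R)):
        core = np.isin(labels, lab)
        dist = ndimage.distance_transform_edt(~core, sampling=sampling)
        box = dist <= cfg.southampton_margin_mm
        box &= (x_mm >= 0) if side == "L" else (x_mm < 0)
        if (
            box[0].any() or box[-1].any()
            or box[:, 0].any() or box[:, -1].any()
            or box[:, :, 0].any() or box[:, :, -1].any()
        ):
            raise ValueError(
                "Southampton VOI touches the volume boundary; margin violated"
            )
        if box.sum() < 3 * core.sum():
            raise ValueError(
                "Southampton VOI smaller than 3x the anatomical striatum; "
                "increase southampton_margin_mm"
            )
        striatal_boxes[side] = box

    brain = labels != OUTSIDE
    reference = (
        brain
        & (labels != RIM)
        & ~striatal_boxes["L"]
        & ~striatal_boxes["R"]
    )
    return VOISet(anatomical, striatal_boxes, reference, geometry.voxel_size_mm)


def _record(volume, method: str, side: str, sbr, c_s, c_ns) -> SBRRecord:
    meta = getattr(volume, "meta", {}) or {}
    return SBRRecord(
        subject_id=meta.get("subject_id", meta.get("camera", "study")),
        side=side,
        method=method,
        recon=meta.get("recon", "truth"),
        camera=meta.get("camera", "unknown"),
        sbr=float(sbr),
        c_s=float(c_s),
        c_ns=float(c_ns),
        age=meta.get("age"),
        sex=meta.get("sex"),
        true_sbr=meta.get(f"true_sbr_{'left' if side == 'L' else 'right'}"),
    )


def brass_sbr(volume, vois: VOISet):
    """BRASS-style SBR from anatomical VOI count concentrations.

    Per side the striatal concentration pools caudate and putamen counts
    over their combined volume; the specific concentration subtracts the
    occipital reference: ``sbr = (c_striatal - c_ns) / c_ns``.
    """
    data = _volume_data(volume)
    vv = vois.voxel_volume_ml
    occ = vois.anatomical["occipital"]
    if not occ.any():
        raise QuantificationError("occipital reference mask is empty")
    c_ns = data[occ].mean() / vv
    if c_ns <= 0:
        raise QuantificationError("non-positive occipital reference concentration")
    out = []
    for side in ("L", "R"):
        mask = vois.anatomical[f"caudate_{side}"] | vois.anatomical[f"putamen_{side}"]
        c_striatal = data[mask].sum() / (mask.sum() * vv)
        c_s = c_striatal - c_ns
        out.append(_record(volume, "brass", side, c_s / c_ns, c_s, c_ns))
    return tuple(out)


def southampton_sbr(volume, vois: VOISet, cfg: QuantConfig | None = None):
    """Southampton (specific uptake size index) SBR.

    Specific counts are total counts in the generous striatal VOI minus
    the background contribution (reference concentration times VOI
    volume); concentration follows by dividing by the assumed striatal
    volume.
    """
    cfg = cfg or QuantConfig()
    data = _volume_data(volume)
    vv = vois.voxel_volume_ml
    ref = vois.southampton_reference
    if not ref.any():
        raise QuantificationError("Southampton reference mask is empty")
    c_ns = data[ref].mean() / vv
    if c_ns <= 0:
        raise QuantificationError("non-positive reference concentration")
    out = []
    for side in ("L", "R"):
        box = vois.southampton_striatal[side]
        specific_counts = data[box].sum() - c_ns * box.sum() * vv
        c_s = specific_counts / cfg.striatal_volume_ml
        out.append(_record(volume, "southampton", side, c_s / c_ns, c_s, c_ns))
    return tuple(out)


def quantify_volume(
    volume,
    geometry: PhantomSpec,
    methods=QUANT_METHODS,
    cfg: QuantConfig | None = None,
) -> "list[SBRRecord]":
    """Run one or both quantifiers on a volume; returns L/R records."""
    cfg = cfg or QuantConfig()
    vois = place_vois(volume, geometry, cfg)
    records: "list[SBRRecord]" = []
    for method in methods:
        if method == "brass":
            records.extend(brass_sbr(volume, vois))
        elif method == "southampton":
            records.extend(southampton_sbr(volume, vois, cfg))
        else:
            raise ValueError(f"unknown quantification method {method!r}")
    return records
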