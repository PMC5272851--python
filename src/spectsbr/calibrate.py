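"""Phantom calibration of measured SBRs.

Scanning the striatal phantom at known filling ratios gives pairs of
(true, measured) SBR per camera, quantification method and reconstruction
regime.  An ordinary least-squares line ``measured = slope * true +
intercept`` is fitted (the uniform 1:1 filling anchors the intercept at
true SBR = 0), and applied in inverse to human measurements:
``sbr_cal = (sbr - intercept) / slope``.  The factor is strictly tied to
its (camera, method, recon) triple — applying it across cameras is the
error calibration exists to prevent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .quantify import SBRRecord


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationFactor:
    camera: str
    method: str  # "brass" | "southampton"
    recon: str  # "FBP" | "IRNC" | "IRAC" | "ACSC"
    slope: float
    intercept: float
    n_points: int
    r_squared: float

    @property
    def key(self):
        return (self.camera, self.method, self.recon)


def fit_calibration(points, camera: str, method: str, recon: str) -> CalibrationFactor:
    """OLS recovery line from (true_sbr, measured_sbr) phantom points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CalibrationError("need at least 3 (true, measured) points")
    true, measured = pts[:, 0], pts[:, 1]
    if len(np.unique(true)) < 2:
        raise CalibrationError("true SBRs must span at least 2 distinct values")
    slope, intercept = np.polyfit(true, measured, 1)
    if slope <= 0:
        raise CalibrationError(
            f"non-positive recovery slope {slope:.3g}; calibration unusable"
        )
    resid = measured - (slope * true + intercept)
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationFactor(
        camera=camera,
        method=method,
        recon=recon,
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(true),
        r_squared=r2,
    )


def apply_calibration(record: SBRRecord, factor: CalibrationFactor) -> SBRRecord:
    """Map a measured SBR back to the true-SBR scale.

    Refuses mismatched (camera, method, recon) triples and double
    application; the uncalibrated value is kept in the record.
    """
    key = (record.camera, record.method, record.recon)
    if key != factor.key:
        raise CalibrationError(
            f"calibration factor {factor.key} does not match record {key}"
        )
    if record.calibrated:
        raise CalibrationError("record is already calibrated")
    return replace(
        record,
        sbr=(record.sbr - factor.intercept) / factor.slope,
        calibrated=True,
        sbr_uncalibrated=record.sbr,
    )


def fit_calibration_table(records) -> "dict[tuple, CalibrationFactor]":
    """Fit one factor per (camera, method, recon) triple from phantom records.

    ``records`` are SBRRecords measured on phantom scans whose ``true_sbr``
    field is set.  Returns a dict keyed by the triple.
    """
    groups: "dict[tuple, list]" = {}
    for r in records:
        if r.true_sbr is None:
            raise CalibrationError(f"record {r.subject_id}/{r.side} lacks true_sbr")
        groups.setdefault((r.camera, r.method, r.recon), []).append(
            (r.true_sbr, r.sbr)
        )
    return {
        key: fit_calibration(pts, *key) for key, pts in groups.items()
    }
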