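"""Normal-database statistics.

Databases are compared with the symmetric percentage difference

    %difference = 100 * (1/2N) * sum_i (A_i - B_i) / ((A_i + B_i)/2)

taken over the 2N per-striatum SBR values (left and right contribute
separately for each of the N subjects), with significance from the paired
t test under a Bonferroni-corrected threshold alpha = 0.05/m.  Age decline
is characterised by OLS of SBR on age over the same 2N values; the 95% CI
band is two standard errors of the regression, and age-corrected summaries
reference the SBR to 65 years.  Raw-projection scatter fractions

    %SC = 100 * (total SC counts / W_SC) / (total PH counts / W_PH)

and their phantom-vs-control percentage difference estimate the
extra-brain contribution to each satellite window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .quantify import SBRRecord
from .simulate import ProjectionSet

logger = logging.getLogger(__name__)


@dataclass
class Database:
    """Per-striatum SBR records sharing one (method, recon, calibrated) label."""

    records: "list[SBRRecord]"
    label: "tuple[str, str, bool]" = None  # (method, recon, calibrated)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("database must contain records")
        labels = {(r.method, r.recon, r.calibrated) for r in self.records}
        if len(labels) != 1:
            raise ValueError(
                f"records mix (method, recon, calibrated) labels: {sorted(labels)}"
            )
        if self.label is None:
            self.label = labels.pop()
        sides: "dict[str, set]" = {}
        for r in self.records:
            sides.setdefault(r.subject_id, set()).add(r.side)
        bad = {s: v for s, v in sides.items() if v != {"L", "R"}}
        if bad:
            raise ValueError(f"subjects without exactly one L and one R record: {bad}")

    @property
    def n_subjects(self) -> int:
        return len({r.subject_id for r in self.records})

    def keyed(self) -> "dict[tuple[str, str], SBRRecord]":
        return {(r.subject_id, r.side): r for r in self.records}

    def values(self) -> np.ndarray:
        return np.array([r.sbr for r in sorted_records(self.records)])

    def ages(self) -> np.ndarray:
        return np.array([r.age for r in sorted_records(self.records)], dtype=float)


def sorted_records(records):
    return sorted(records, key=lambda r: (r.subject_id, r.side))


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # SBR / year
    intercept: float  # SBR at age 0
    se_regression: float  # residual standard error, SBR units
    n: int

    @property
    def ci_halfwidth(self) -> float:
        """95% CI half-width: two standard errors of the regression."""
        return 2.0 * self.se_regression

    def predict(self, age):
        return self.intercept + self.slope * np.asarray(age, dtype=float)


@dataclass(frozen=True)
class ComparisonResult:
    pct_difference: float
    t_stat: float
    p_value: float
    m: int
    n_pairs: int

    @property
    def alpha_corrected(self) -> float:
        return 0.05 / self.m

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_corrected


@dataclass(frozen=True)
class ScatterFractionResult:
    pct_sc_l: float
    pct_sc_u: float
    extra_brain_pct_l: float | None = None
    extra_brain_pct_u: float | None = None


def _paired_values(A: Database, B: Database):
    ka, kb = A.keyed(), B.keyed()
    if set(ka) != set(kb):
        missing = sorted(set(ka) ^ set(kb))
        raise ValueError(f"databases are not paired; mismatched keys: {missing[:10]}")
    keys = sorted(ka)
    a = np.array([ka[k].sbr for k in keys])
    b = np.array([kb[k].sbr for k in keys])
    return a, b


def percent_difference(A: Database, B: Database) -> float:
    """Symmetric mean percentage difference over all paired striata."""
    a, b = _paired_values(A, B)
    denom = (a + b) / 2.0
    ok = denom != 0
    if not ok.all():
        logger.warning(
            "percent_difference: excluding %d double-zero pair(s)", (~ok).sum()
        )
    if not ok.any():
        raise ValueError("all pairs have zero denominator")
    return float(100.0 * np.mean((a[ok] - b[ok]) / denom[ok]))


def paired_compare(A: Database, B: Database, m: int = 1) -> ComparisonResult:
    """Paired t test on the 2N striatal SBRs with Bonferroni threshold."""
    if m < 1:
        raise ValueError("m (number of hypotheses) must be >= 1")
    a, b = _paired_values(A, B)
    if len(a) < 3:
        raise ValueError("need at least 3 paired values")
    d = a - b
    if np.allclose(d, 0.0):
        t_stat, p_value = 0.0, 1.0
    elif np.ptp(d) == 0.0:
        # constant non-zero difference: zero variance, certain rejection
        t_stat, p_value = float(np.sign(d[0]) * np.inf), 0.0
    else:
        t_stat, p_value = stats.ttest_rel(a, b)
    return ComparisonResult(
        pct_difference=percent_difference(A, B),
        t_stat=float(t_stat),
        p_value=float(p_value),
        m=m,
        n_pairs=len(a),
    )


def scatter_fraction(p: ProjectionSet) -> ScatterFractionResult:
    """Satellite-window count densities relative to the photopeak (%)."""
    if p.w_sc <= 0 or p.w_ph <= 0:
        raise ValueError("window widths must be positive")
    ph = p.ph.sum()
    if ph <= 0:
        raise ValueError("photopeak contains no counts")
    return ScatterFractionResult(
        pct_sc_l=float(100.0 * (p.sc_l.sum() / p.w_sc) / (ph / p.w_ph)),
        pct_sc_u=float(100.0 * (p.sc_u.sum() / p.w_sc) / (ph / p.w_ph)),
    )


def extra_brain_contribution(controls, phantoms) -> ScatterFractionResult:
    """Phantom-vs-control %SC difference per window (extra-brain estimate).

    ``controls`` and ``phantoms`` are lists of ScatterFractionResult from
    one camera.  Returns the camera averages with the symmetric percentage
    difference 100 * (controls - phantom) / average per window.
    """
    if not controls or not phantoms:
        raise ValueError("both control and phantom result lists must be non-empty")

    def diff(c: float, ph: float) -> float:
        avg = (c + ph) / 2.0
        if avg == 0:
            raise ValueError("undefined percentage difference: both averages zero")
        return 100.0 * (c - ph) / avg

    c_l = float(np.mean([r.pct_sc_l for r in controls]))
    c_u = float(np.mean([r.pct_sc_u for r in controls]))
    p_l = float(np.mean([r.pct_sc_l for r in phantoms]))
    p_u = float(np.mean([r.pct_sc_u for r in phantoms]))
    return ScatterFractionResult(
        pct_sc_l=c_l,
        pct_sc_u=c_u,
        extra_brain_pct_l=diff(c_l, p_l),
        extra_brain_pct_u=diff(c_u, p_u),
    )


def fit_age_regression(db: Database) -> RegressionResult:
    """OLS of per-striatum SBR on age; residual SE defines the CI band."""
    ages = db.ages()
    if np.isnan(ages).any():
        raise ValueError("all records need an age for the regression")
    if len(np.unique(ages)) < 3:
        raise ValueError("need at least 3 distinct ages")
    y = db.values()
    X = np.column_stack([np.ones_like(ages), ages])
    beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 2
    se = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return RegressionResult(
        slope=float(beta[1]), intercept=float(beta[0]), se_regression=se, n=len(y)
    )


def summarize_database(
    db: Database, reg: RegressionResult | None = None, ref_age: float = 65.0
):
    """Age-corrected mean, SD and CoV% of a database.

    Each striatal value is referenced to ``ref_age`` along the fitted
    decline: ``sbr' = sbr + slope * (ref_age - age)``.
    """
    reg = reg or fit_age_regression(db)
    corrected = db.values() + reg.slope * (ref_age - db.ages())
    mean = float(corrected.mean())
    sd = float(corrected.std(ddof=1))
    if mean <= 0:
        logger.warning("summarize_database: non-positive mean; CoV undefined")
        return mean, sd, float("nan")
    return mean, sd, float(100.0 * sd / mean)


def build_database(records, method: str, recon: str, calibrated: bool) -> Database:
    """Select one (method, recon, calibrated) cell from a record pool."""
    sel = [
        r
        for r in records
        if r.method == method and r.recon == recon and r.calibrated == calibrated
    ]
    return Database(sel)
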