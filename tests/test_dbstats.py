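"""Database statistics: percentage difference, paired tests, age regression."""

import numpy as np
import pytest
from scipy import stats

from spectsbr import (
    Database,
    ProjectionSet,
    SBRRecord,
    extra_brain_contribution,
    fit_age_regression,
    paired_compare,
    percent_difference,
    scatter_fraction,
    summarize_database,
)
from spectsbr.dbstats import ScatterFractionResult


def _db(values, ages=None, method="brass", recon="ACSC", calibrated=False):
    """One record per (subject, side) from a flat list of 2N values."""
    records = []
    for i, v in enumerate(values):
        records.append(
            SBRRecord(
                subject_id=f"s{i // 2:03d}",
                side="L" if i % 2 == 0 else "R",
                method=method,
                recon=recon,
                camera="cam",
                sbr=float(v),
                c_s=float(v),
                c_ns=1.0,
                calibrated=calibrated,
                age=None if ages is None else float(ages[i // 2]),
            )
        )
    return Database(records)


class TestPercentDifference:
    def test_identical_databases_zero(self):
        a = _db([1, 2, 3, 4])
        assert percent_difference(a, a) == 0.0

    def test_hand_example_two_vs_one(self):
        a = _db([2.0] * 8)
        b = _db([1.0] * 8)
        assert percent_difference(a, b) == pytest.approx(100.0 / 1.5, rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = _db(rng.uniform(1, 9, 10))
        b = _db(rng.uniform(1, 9, 10))
        assert percent_difference(a, b) == pytest.approx(
            -percent_difference(b, a), rel=1e-12
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        va, vb = rng.uniform(1, 9, 10), rng.uniform(1, 9, 10)
        base = percent_difference(_db(va), _db(vb))
        scaled = percent_difference(_db(va * 3.7), _db(vb * 3.7))
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_unpaired_keys_rejected(self):
        a = _db([1, 2, 3, 4])
        b = Database(
            [
                SBRRecord(f"other{i}", s, "brass", "ACSC", "cam", 1.0, 1.0, 1.0)
                for i in range(2)
                for s in ("L", "R")
            ]
        )
        with pytest.raises(ValueError, match="paired"):
            percent_difference(a, b)

    def test_double_zero_pairs_excluded(self, caplog):
        a = _db([0.0, 2.0, 3.0, 4.0])
        b = _db([0.0, 1.0, 1.0, 1.0])
        with caplog.at_level("WARNING"):
            out = percent_difference(a, b)
        # only the three non-degenerate pairs contribute
        manual = 100 * np.mean([1 / 1.5, 2 / 2.0, 3 / 2.5])
        assert out == pytest.approx(manual)


class TestPairedCompare:
    def test_equal_databases_not_significant(self):
        a = _db([1, 2, 3, 4, 5, 6])
        res = paired_compare(a, a, m=4)
        assert res.p_value == 1.0
        assert not res.significant

    def test_bonferroni_threshold(self):
        a = _db([1, 2, 3, 4, 5, 6])
        res = paired_compare(a, _db([2, 3, 4, 5, 6, 7]), m=4)
        assert res.alpha_corrected == pytest.approx(0.0125)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        va, vb = rng.uniform(1, 9, 12), rng.uniform(1, 9, 12)
        res = paired_compare(_db(va), _db(vb))
        assert res.p_value == pytest.approx(stats.ttest_rel(va, vb)[1])

    def test_type_one_error_rate_under_null(self):
        # paired t at alpha = 0.05 rejects ~5% of null replicates
        rng = np.random.default_rng(3)
        n, reps, hits = 60, 1000, 0
        for _ in range(reps):
            va = rng.normal(5, 1, n)
            vb = rng.normal(5, 1, n)
            if paired_compare(_db(va), _db(vb), m=1).significant:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.015)

    def test_too_few_pairs_rejected(self):
        a = _db([1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            paired_compare(a, a)


class TestScatterFraction:
    def test_empty_satellites_zero(self):
        p = ProjectionSet(
            np.full((2, 4, 4), 10.0), np.zeros((2, 4, 4)), np.zeros((2, 4, 4)),
            angles=[0.0, 90.0],
        )
        r = scatter_fraction(p)
        assert r.pct_sc_l == 0.0 and r.pct_sc_u == 0.0

    def test_hand_example(self):
        # total SC_l = 70, total PH = 3200, widths 7/32 -> 10%
        ph = np.full((1, 8, 8), 3200.0 / 64)
        sc = np.full((1, 8, 8), 70.0 / 64)
        p = ProjectionSet(ph, sc, np.zeros_like(ph), angles=[0.0])
        assert scatter_fraction(p).pct_sc_l == pytest.approx(10.0)

    def test_empty_photopeak_rejected(self):
        p = ProjectionSet(
            np.zeros((1, 4, 4)), np.zeros((1, 4, 4)), np.zeros((1, 4, 4)),
            angles=[0.0],
        )
        with pytest.raises(ValueError, match="photopeak"):
            scatter_fraction(p)


class TestExtraBrain:
    def test_identical_averages_zero(self):
        r = ScatterFractionResult(50.0, 30.0)
        out = extra_brain_contribution([r], [r])
        assert out.extra_brain_pct_l == 0.0
        assert out.extra_brain_pct_u == 0.0

    def test_hand_example(self):
        c = ScatterFractionResult(50.0, 60.0)
        p = ScatterFractionResult(50.0, 40.0)
        out = extra_brain_contribution([c], [p])
        assert out.extra_brain_pct_l == 0.0
        assert out.extra_brain_pct_u == pytest.approx(40.0)

    def test_both_zero_rejected(self):
        c = ScatterFractionResult(0.0, 60.0)
        p = ScatterFractionResult(0.0, 40.0)
        with pytest.raises(ValueError, match="undefined"):
            extra_brain_contribution([c], [p])

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            extra_brain_contribution([], [ScatterFractionResult(1, 1)])


class TestAgeRegression:
    def test_noise_free_linear_exact(self):
        ages = np.array([40, 50, 60, 70, 80.0])
        values = np.repeat(10.0 - 0.05 * ages, 2)
        db = _db(values, ages=ages)
        reg = fit_age_regression(db)
        assert reg.slope == pytest.approx(-0.05)
        assert reg.intercept == pytest.approx(10.0)
        assert reg.se_regression == pytest.approx(0.0, abs=1e-10)
        assert reg.ci_halfwidth == pytest.approx(2 * reg.se_regression)

    def test_recovers_generated_decline(self):
        rng = np.random.default_rng(4)
        n = 200
        ages = rng.uniform(30, 90, n)
        truth = 12.0 - 0.05 * ages
        values = np.repeat(truth, 2) + rng.normal(0, 0.5, 2 * n)
        db = _db(values, ages=ages)
        reg = fit_age_regression(db)
        se_slope = 0.5 / np.sqrt(2 * np.sum((ages - ages.mean()) ** 2))
        assert abs(reg.slope + 0.05) < 2 * se_slope * 1.5

    def test_ci_band_coverage(self):
        rng = np.random.default_rng(5)
        n = 500
        ages = rng.uniform(30, 90, n)
        values = np.repeat(10 - 0.05 * ages, 2) + rng.normal(0, 0.8, 2 * n)
        db = _db(values, ages=ages)
        reg = fit_age_regression(db)
        resid = db.values() - reg.predict(db.ages())
        frac = np.mean(np.abs(resid) <= reg.ci_halfwidth)
        assert frac == pytest.approx(0.95, abs=0.03)

    def test_constant_age_rejected(self):
        db = _db([1, 2, 3, 4], ages=[50, 50])
        with pytest.raises(ValueError, match="distinct"):
            fit_age_regression(db)


class TestSummaries:
    def test_reference_age_subjects_unchanged(self):
        db = _db([3.0, 3.5, 4.0, 4.5, 5.0, 5.5], ages=[65, 65, 65])
        reg = fit_age_regression(
            _db([3, 3.5, 4, 4.5, 5, 5.5], ages=[40, 60, 80])
        )
        mean, sd, cov = summarize_database(db, reg)
        vals = np.array([3.0, 3.5, 4.0, 4.5, 5.0, 5.5])
        assert mean == pytest.approx(vals.mean())
        assert sd == pytest.approx(vals.std(ddof=1))

    def test_perfect_detrending(self):
        ages = np.array([40, 50, 60, 70, 80.0])
        db = _db(np.repeat(10 - 0.05 * ages, 2), ages=ages)
        mean, sd, cov = summarize_database(db)
        assert sd == pytest.approx(0.0, abs=1e-10)
        assert mean == pytest.approx(10 - 0.05 * 65)

    def test_corrected_sd_recovers_biological_spread(self):
        rng = np.random.default_rng(6)
        n = 200
        ages = rng.uniform(30, 90, n)
        values = np.repeat(12 - 0.05 * ages, 2) + rng.normal(0, 0.5, 2 * n)
        db = _db(values, ages=ages)
        _, sd, _ = summarize_database(db)
        assert sd == pytest.approx(0.5, rel=0.15)


class TestDatabaseValidation:
    def test_mixed_labels_rejected(self):
        recs = _db([1, 2, 3, 4]).records + _db([1, 2], method="southampton").records
        with pytest.raises(ValueError, match="mix"):
            Database(recs)

    def test_missing_side_rejected(self):
        rec = SBRRecord("solo", "L", "brass", "ACSC", "cam", 1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="exactly one L and one R"):
            Database([rec])
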