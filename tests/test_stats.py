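"""Correlations, paired laterality tests, and the power design formula."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from jointpet.stats import (
    cohort_analysis,
    corr_pvalue,
    min_detectable_r,
    paired_t,
    pearson_corr,
    validate_cohort_table,
)
from jointpet.synthetic import CohortSpec, make_cohort


def _vectorized_pearson_p(x, y):
    """Independent vectorized r/p computation for Monte-Carlo checks."""
    n = x.shape[1]
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    return r, 2 * sps.t.sf(np.abs(t), n - 2)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_corr(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_five_point_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        # brute-force covariance / standard deviation computation
        r_oracle = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        res = pearson_corr(x, y)
        assert res.r == pytest.approx(r_oracle, rel=1e-12)
        assert res.n_used == 5

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        res = pearson_corr(x, y)
        assert res.n_used == 3
        assert res.r == pytest.approx(1.0)

    def test_degenerate_variable_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_corr([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_insufficient_n_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_corr([1.0, 2.0], [3.0, 4.0])

    def test_p_and_r_mutually_consistent(self, rng):
        x, y = rng.normal(size=(2, 25))
        res = pearson_corr(x, y)
        assert res.p == corr_pvalue(res.r, res.n_used)

    def test_null_p_uniform(self, rng):
        """Under independence, Pearson p-values are uniform on [0, 1]."""
        reps, n = 10_000, 18
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        _, p = _vectorized_pearson_p(x, y)
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestCorrPvalue:
    def test_zero_r_gives_p_one(self):
        assert corr_pvalue(0.0, 18) == pytest.approx(1.0)
        assert corr_pvalue(0.0, 5) == pytest.approx(1.0)

    def test_knee_fdg_naf_claim(self):
        """r = 0.77 at n = 18 is significant below the 0.001 level."""
        assert corr_pvalue(0.77, 18) < 0.001

    def test_limit_at_unit_correlation(self):
        assert corr_pvalue(1.0, 10) == 0.0
        assert corr_pvalue(-1.0, 10) == 0.0

    def test_strictly_decreasing_in_abs_r(self):
        ps = [corr_pvalue(r, 18) for r in np.linspace(0.0, 0.99, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_agrees_with_permutation_oracle(self, rng):
        n, rho = 18, 0.6
        x = rng.standard_normal(n)
        y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        res = pearson_corr(x, y)
        perms = 20_000
        xc = x - x.mean()
        yc = y - y.mean()
        denom = math.sqrt((xc**2).sum() * (yc**2).sum())
        r_perm = np.empty(perms)
        for i in range(perms):
            r_perm[i] = (xc * rng.permutation(yc)).sum() / denom
        p_perm = (np.abs(r_perm) >= abs(res.r) - 1e-12).mean()
        se = math.sqrt(max(p_perm * (1 - p_perm), 1e-6) / perms)
        assert abs(res.p - p_perm) < max(5 * se, 0.01)


class TestPairedT:
    def test_identical_sides(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_equals_one_sample_t_on_differences(self, rng):
        left = rng.normal(size=15)
        right = left + rng.normal(0.2, 0.5, size=15)
        res = paired_t(left, right)
        one = sps.ttest_1samp(right - left, 0.0)
        assert res.t == pytest.approx(one.statistic)
        assert res.p == pytest.approx(one.pvalue)
        assert math.copysign(1, res.t) == math.copysign(1, res.mean_difference)

    def test_shift_invariance(self, rng):
        left = rng.normal(size=12)
        right = rng.normal(size=12)
        a = paired_t(left, right)
        b = paired_t(left + 5.0, right + 5.0)
        assert a.t == pytest.approx(b.t) and a.p == pytest.approx(b.p)

    def test_rejection_rate_matches_analytic_power(self, rng):
        """Paired-t rejection under a shift matches noncentral-t power."""
        n, delta, sd, reps = 10, 0.6, 1.0, 10_000
        diffs = rng.normal(delta, sd, size=(reps, n))
        t = diffs.mean(1) / (diffs.std(1, ddof=1) / math.sqrt(n))
        crit = sps.t.ppf(0.975, n - 1)
        emp = (np.abs(t) > crit).mean()
        nc = delta / (sd / math.sqrt(n))
        analytic = (
            sps.nct.sf(crit, n - 1, nc) + sps.nct.cdf(-crit, n - 1, nc)
        )
        assert emp == pytest.approx(analytic, abs=0.015)


class TestMinDetectableR:
    def test_design_value_at_n18(self):
        assert min_detectable_r(18, 0.8, 0.05) == pytest.approx(0.62, abs=0.01)

    def test_monotone_decreasing_in_n(self):
        rs = [min_detectable_r(n) for n in range(10, 101, 5)]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_satisfies_fisher_z_identity(self):
        r = min_detectable_r(40, 0.8, 0.05)
        z_sum = sps.norm.ppf(0.975) + sps.norm.ppf(0.8)
        assert (z_sum / math.atanh(r)) ** 2 + 3 == pytest.approx(40, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_detectable_r(3)
        with pytest.raises(ValueError):
            min_detectable_r(18, power=1.2)

    def test_empirical_power_at_returned_r(self, rng):
        """The design is approximate and slightly conservative at small n:
        simulated power at the returned r is at or above the target, and
        close to it at moderate n where the approximation is accurate."""
        for n, hi in ((18, 0.86), (50, 0.83)):
            r = min_detectable_r(n)
            reps = 10_000
            x = rng.standard_normal((reps, n))
            y = r * x + math.sqrt(1 - r**2) * rng.standard_normal((reps, n))
            _, p = _vectorized_pearson_p(x, y)
            power = (p < 0.05).mean()
            assert 0.78 <= power <= hi


class TestCohortAnalysis:
    def test_designed_correlation_recovered(self):
        table = make_cohort(CohortSpec(n=300, seed=42))
        rep = cohort_analysis(table)
        r = rep.correlations["knee"][("naf", "r")]["bmi"]
        # 95% CI of the designed rho = 0.50 at n = 300 via Fisher z
        lo, hi = np.tanh(np.arctanh(0.5) + np.array([-1, 1]) * 1.96 / np.sqrt(297))
        assert lo < r < hi

    def test_single_subject_all_unavailable(self):
        table = make_cohort(CohortSpec(n=1, seed=0))
        rep = cohort_analysis(table)
        for df in rep.correlations.values():
            assert df.loc[:, (slice(None), "r")].isna().all().all()

    def test_row_order_invariance(self):
        table = make_cohort(CohortSpec(n=30, seed=7))
        rep_a = cohort_analysis(table)
        rep_b = cohort_analysis(table.sample(frac=1.0, random_state=1))
        for joint in rep_a.correlations:
            a = rep_a.correlations[joint]
            b = rep_b.correlations[joint]
            np.testing.assert_allclose(a.to_numpy(float), b.to_numpy(float), atol=1e-12)

    def test_laterality_tests_present(self):
        table = make_cohort(CohortSpec(n=20, seed=3))
        rep = cohort_analysis(table)
        pairs = {(t.joint, t.tracer) for t in rep.laterality}
        assert pairs == {(j, t) for j in ("knee", "hip", "si") for t in ("fdg", "naf")}

    def test_right_handed_filter_reduces_n(self):
        table = make_cohort(CohortSpec(n=40, seed=9))
        full = cohort_analysis(table)
        sub = cohort_analysis(table, right_handed_only=True)
        n_right = (table["handedness"] == "right").sum()
        assert all(t.n_pairs == n_right for t in sub.laterality)
        assert all(t.n_pairs == 40 for t in full.laterality)

    def test_bh_qvalues_bounded(self):
        table = make_cohort(CohortSpec(n=25, seed=5))
        rep = cohort_analysis(table, bh_qvalues=True)
        for df in rep.correlations.values():
            q = df.loc[:, (slice(None), "q")].to_numpy(float)
            p = df.loc[:, (slice(None), "p")].to_numpy(float)
            ok = np.isfinite(q)
            assert np.all(q[ok] >= p[ok] - 1e-12) and np.all(q[ok] <= 1.0)

    def test_duplicate_subjects_rejected(self):
        table = make_cohort(CohortSpec(n=5, seed=0))
        table.loc[1, "subject"] = table.loc[0, "subject"]
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort_table(table)

    def test_bmi_consistency_checked(self):
        table = make_cohort(CohortSpec(n=5, seed=0))
        table.loc[2, "bmi"] += 5.0
        with pytest.raises(ValueError, match="BMI"):
            validate_cohort_table(table)
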