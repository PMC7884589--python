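"""Frequentist statistics: paired t, effect sizes, BCa bootstrap, ICC."""

import numpy as np
import pytest
from scipy import stats as sps

from pasbayes import stats
from pasbayes.exceptions import InputError, UndefinedStatisticError


class TestPairedT:
    def test_symmetric_perturbation_gives_t_zero(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        post = pre + np.array([0.5, -0.5, 0.5, -0.5])
        t, df, p = stats.paired_t_one_tailed(pre, post)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)
        assert df == 3

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        pre, post = rng.normal(size=(2, 14))
        _, df, _ = stats.paired_t_one_tailed(pre, post + 0.5)
        assert df == 13

    def test_hand_formula_oracle(self):
        pre = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
        post = np.array([11.5, 12.0, 10.0, 12.5, 12.0])
        diff = post - pre
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
        t, df, p = stats.paired_t_one_tailed(pre, post)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(float(sps.t.sf(t_hand, 4)), rel=1e-12)

    def test_negative_t_gives_large_p(self):
        pre = np.array([2.0, 3.0, 4.0, 5.0])
        t, _, p = stats.paired_t_one_tailed(pre, pre - [0.5, 0.6, 0.4, 0.5])
        assert t < 0 and p > 0.5

    def test_zero_variance_error(self):
        pre = np.array([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedStatisticError):
            stats.paired_t_one_tailed(pre, pre + 1.0)


class TestCohensD:
    def test_null_and_unit_shift(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        assert stats.cohens_d_pre(pre, pre) == 0.0
        assert stats.cohens_d_pre(pre, pre + pre.std(ddof=1)) == \
            pytest.approx(1.0)

    def test_brute_force_formula(self):
        rng = np.random.default_rng(5)
        pre = rng.normal(10, 2, 12)
        post = rng.normal(11, 2, 12)
        assert stats.cohens_d_pre(pre, post) == pytest.approx(
            (post - pre).mean() / pre.std(ddof=1), rel=1e-12)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(6)
        pre = rng.normal(10, 2, 10)
        post = rng.normal(11, 2, 10)
        d = stats.cohens_d_pre(pre, post)
        assert stats.cohens_d_pre(pre + 7, post + 7) == pytest.approx(d)
        assert stats.cohens_d_pre(3 * pre, 3 * post) == pytest.approx(d)
        t1 = stats.paired_t_one_tailed(pre, post)[0]
        t2 = stats.paired_t_one_tailed(pre + 7, post + 7)[0]
        assert t1 == pytest.approx(t2)


class TestBetweenConditionD:
    def test_equal_changes_give_zero(self):
        rng = np.random.default_rng(7)
        delta = rng.normal(0, 1, 10)
        assert stats.between_condition_d(delta, delta) == 0.0

    def test_brute_force_formula(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.0, 1.0, 14)
        s = rng.normal(0.0, 1.0, 14)
        assert stats.between_condition_d(a, s) == pytest.approx(
            (a - s).mean() / s.std(ddof=1), rel=1e-12)


class TestBCa:
    def test_forced_zero_reduces_to_percentile(self):
        assert stats.bca_percentiles(0.0, 0.0) == pytest.approx((0.025, 0.975))

    def test_degenerate_data_collapse(self):
        pre = np.array([2.0, 2.0, 2.0, 2.0, 3.0])
        post = pre + 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = stats.bca_ci(lambda a, b: float(np.median(b - a)),
                                  (pre, post), n_boot=50, seed=0)
        assert lo == hi

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(10, 2, 14)
        post = rng.normal(11, 2, 14)
        d = stats.cohens_d_pre(pre, post)
        lo, hi = stats.bca_ci(stats.cohens_d_pre, (pre, post),
                              n_boot=2000, seed=0)
        assert lo <= d <= hi

    def test_against_scipy_bca(self):
        """Cross-check endpoints against scipy's independent BCa machinery."""
        rng = np.random.default_rng(2)
        pre = rng.normal(10, 2, 14)
        post = pre + rng.normal(1, 1.5, 14)
        ours = stats.bca_ci(stats.cohens_d_pre, (pre, post),
                            n_boot=9999, seed=3)
        res = sps.bootstrap(
            (pre, post), lambda a, b, axis=-1:
                (b - a).mean(axis=axis) / a.std(ddof=1, axis=axis),
            paired=True, vectorized=True, method="BCa", n_resamples=9999,
            confidence_level=0.95, rng=np.random.default_rng(4))
        lo, hi = res.confidence_interval
        assert ours[0] == pytest.approx(lo, abs=0.05)
        assert ours[1] == pytest.approx(hi, abs=0.05)


class TestIcc3:
    def test_offset_columns_perfect_consistency(self):
        rng = np.random.default_rng(0)
        base = rng.normal(50, 10, 8)
        mat = np.column_stack([base, base + 5.0, base - 3.0])
        assert stats.icc3(mat) == pytest.approx(1.0)

    def test_session_constant_invariance(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(50, 10, (10, 3))
        shifted = mat + np.array([0.0, 7.0, -4.0])
        assert stats.icc3(shifted) == pytest.approx(stats.icc3(mat))

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [stats.icc3(rng.normal(0, 1, (14, 3))) for _ in range(200)]
        assert abs(np.mean(vals)) < 0.05

    def test_mean_squares_hand_computation(self):
        """Toy 6 x 3 matrix: explicit two-way ANOVA mean squares."""
        rng = np.random.default_rng(11)
        x = rng.normal(40, 8, (6, 3)).round(1)
        n, k = x.shape
        grand = x.mean()
        bms = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        resid = x - x.mean(axis=1, keepdims=True) \
            - x.mean(axis=0, keepdims=True) + grand
        ems = (resid ** 2).sum() / ((n - 1) * (k - 1))
        expected = (bms - ems) / (bms + (k - 1) * ems)
        assert stats.icc3(x) == pytest.approx(expected, rel=1e-12)

    def test_against_pingouin(self):
        """Independent oracle: pingouin's ICC3 on the same matrix."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(21)
        x = rng.normal(30, 6, (10, 3))
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 3),
            "raters": np.tile(["a", "b", "c"], 10),
            "score": x.ravel(),
        })
        icc = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="score")
        ref = float(icc.loc[icc["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert stats.icc3(x) == pytest.approx(ref, abs=1e-9)

    def test_incomplete_matrix_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(InputError):
            stats.icc3(x)


class TestNormality:
    def test_range_check(self):
        with pytest.raises(InputError):
            stats.normality_check([1.0, 2.0])

    def test_skewed_samples_rejected_often(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            stats.normality_check(rng.exponential(1.0, 50))[1] < 0.05
            for _ in range(100))
        assert rejections > 50

    def test_null_p_uniformity(self):
        """p-values under normal samples are uniform (KS check, n=14)."""
        rng = np.random.default_rng(9)
        ps = [stats.normality_check(rng.normal(0, 1, 14))[1]
              for _ in range(300)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01
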