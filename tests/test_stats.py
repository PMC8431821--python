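"""Inferential battery: ANOVA, pairwise tests, TOST, cluster permutation, power."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from stridelearn.stats import (
    cluster_permutation,
    cohen_dz,
    normality_and_variance_checks,
    paired_t_power,
    pairwise_bonferroni,
    required_sample_size,
    rm_anova,
    slope_test,
    tost,
)


def _table(rng, n=18, effects=(0.0, 0.0, 0.0), noise=1.0):
    subj = rng.normal(0, 1.0, n)[:, None]
    data = subj + np.asarray(effects)[None, :] + rng.normal(0, noise, (n, 3))
    return pd.DataFrame(data, columns=["constant", "LV", "HV"])


class TestRmAnova:
    def test_no_variation_zero_F(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]})
        res = rm_anova(table)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.eta_p2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_sums_of_squares(self):
        # independent oracle: textbook SS decomposition on a 4x3 table
        table = pd.DataFrame(
            {"c1": [3.0, 5.0, 6.0, 2.0], "c2": [4.0, 6.0, 8.0, 5.0], "c3": [6.0, 7.0, 9.0, 6.0]}
        )
        x = table.to_numpy()
        grand = x.mean()
        ss_cond = 4 * ((x.mean(axis=0) - grand) ** 2).sum()
        ss_subj = 3 * ((x.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((x - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        f_oracle = (ss_cond / 2) / (ss_err / 6)
        res = rm_anova(table)
        assert res.F == pytest.approx(f_oracle)
        assert res.df_effect == 2 and res.df_error == 6
        assert res.ss_effect == pytest.approx(ss_cond)
        assert res.ss_error == pytest.approx(ss_err)
        assert res.eta_p2 == pytest.approx(ss_cond / (ss_cond + ss_err))

    def test_planted_effect_detected(self, rng):
        res = rm_anova(_table(rng, effects=(0.0, 2.0, 4.0), noise=0.5))
        assert res.p < 0.001 and res.eta_p2 > 0.5

    def test_two_conditions_equals_squared_paired_t(self, rng):
        table = _table(rng)[["constant", "LV"]]
        res = rm_anova(table)
        t, _ = sps.ttest_rel(table["constant"], table["LV"])
        assert res.F == pytest.approx(t**2)


class TestPairwise:
    def test_identical_pair(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5], "c": [2.0, 3, 4, 5, 7]})
        res = pairwise_bonferroni(table).set_index(["A", "B"])
        row = res.loc[("a", "b")]
        assert row["t"] == 0.0 and row["dz"] == 0.0

    def test_bonferroni_correction_factor(self, rng):
        table = _table(rng, effects=(0.0, 0.5, 1.0))
        res = pairwise_bonferroni(table)
        np.testing.assert_allclose(
            res["p_bonf"], np.minimum(1.0, 3 * res["p_raw"]), atol=1e-12
        )

    def test_matches_independent_oracle(self, rng):
        table = _table(rng, effects=(0.0, 1.0, 0.3))
        res = pairwise_bonferroni(table).set_index(["A", "B"])
        for a, b in (("constant", "LV"), ("constant", "HV"), ("LV", "HV")):
            d = table[a].to_numpy() - table[b].to_numpy()
            t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
            assert res.loc[(a, b), "t"] == pytest.approx(t_oracle)
            assert res.loc[(a, b), "dz"] == pytest.approx(d.mean() / d.std(ddof=1))


class TestTost:
    def test_zero_differences_large_n_equivalent(self, rng):
        d = rng.normal(0, 1.0, 200)
        d = d - d.mean()  # exactly zero mean effect
        assert tost(d).equivalent

    def test_effect_at_bound_gives_half_p(self, rng):
        d = rng.normal(size=30)
        d = (d - d.mean()) / d.std(ddof=1)  # mean 0, sd 1
        d = d + 0.3  # effect exactly at the d_z bound
        res = tost(d, bound_dz=0.3)
        assert res.p_upper == pytest.approx(0.5)

    def test_huge_effect_not_equivalent(self, rng):
        d = rng.normal(5.0, 0.5, 20)
        assert not tost(d).equivalent

    def test_matches_pingouin(self, rng):
        d = rng.normal(0.1, 1.0, 18)
        bound = 0.3 * d.std(ddof=1)
        res = tost(d, bound_dz=0.3)
        pg_p = float(pg.tost(d, y=0.0, bound=bound, paired=False)["pval"].iloc[0])
        assert res.p == pytest.approx(pg_p, rel=1e-6)

    def test_never_equivalent_when_t_rejects_beyond_bound(self, rng):
        # effects well beyond the bound: standard t rejects, TOST must not
        # declare equivalence
        for i in range(20):
            r = np.random.default_rng(i)
            d = r.normal(1.0, 1.0, 18)
            _, p_t = sps.ttest_1samp(d, 0.0)
            res = tost(d, bound_dz=0.3)
            if p_t < 0.05 and abs(cohen_dz(d)) > 0.3:
                assert not res.equivalent


class TestClusterPermutation:
    def test_identical_inputs_p_one(self, rng):
        a = rng.normal(size=(10, 60))
        res = cluster_permutation(a, a.copy(), n_perm=200, seed=0)
        assert res.p == 1.0 and res.mass == 0.0

    def test_planted_offset_detected(self, rng):
        a = rng.normal(0, 1.0, (18, 90))
        b = a + rng.normal(0, 1.0, (18, 90)) * 0.1
        b[:, 30:60] += 5.0  # 30-stride offset of 5, noise SD ~1
        res = cluster_permutation(a, b, n_perm=1000, seed=1)
        assert res.p < 0.01
        start, stop = res.cluster
        assert 8 <= start <= 12 and 18 <= stop <= 22  # bins 10..20 of 3 strides

    def test_shift_invariance(self, rng):
        a = rng.normal(size=(12, 60))
        b = rng.normal(size=(12, 60))
        r1 = cluster_permutation(a, b, n_perm=500, seed=3)
        r2 = cluster_permutation(a + 7.0, b + 7.0, n_perm=500, seed=3)
        assert r1.p == r2.p and r1.mass == pytest.approx(r2.mass)

    def test_type_one_error_calibrated(self):
        # scaled-down null calibration; the full-size run lives in acceptance
        rng = np.random.default_rng(202)
        hits = 0
        n = 300
        for i in range(n):
            a = rng.normal(size=(18, 90))
            b = rng.normal(size=(18, 90))
            if cluster_permutation(a, b, n_perm=400, seed=i).p < 0.05 :
                hits += 1
        rate = hits / n
        assert abs(rate - 0.05) < 0.03

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="equal shapes"):
            cluster_permutation(rng.normal(size=(5, 30)), rng.normal(size=(5, 33)))


class TestSlopeTest:
    def test_constant_y_zero_slopes(self):
        x = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        y = pd.DataFrame(np.ones((4, 3)))
        res = slope_test(x, y)
        assert res.mean_slope == 0.0 and res.t == 0.0

    def test_exact_linear_relation(self, rng):
        x = pd.DataFrame(rng.normal(5, 2, (10, 3)))
        y = -0.5 * x
        res = slope_test(x, y)
        assert res.mean_slope == pytest.approx(-0.5)
        np.testing.assert_allclose(res.slopes, -0.5)

    def test_matches_two_point_oracle(self, rng):
        # two conditions: slope is rise over run
        x = pd.DataFrame(rng.normal(size=(6, 2)))
        y = pd.DataFrame(rng.normal(size=(6, 2)))
        res = slope_test(x, y)
        oracle = (y[1] - y[0]) / (x[1] - x[0])
        np.testing.assert_allclose(res.slopes, oracle)


class TestPower:
    def test_study_sample_size(self):
        assert required_sample_size(0.91, alpha=0.05, power=0.90) == 15

    def test_huge_effect_minimal_n(self):
        assert required_sample_size(1e6) == 2

    def test_monotone_in_effect_size(self):
        ns = [required_sample_size(d) for d in (0.3, 0.5, 0.7, 0.91, 1.2, 2.0)]
        assert ns == sorted(ns, reverse=True)

    def test_power_at_returned_n(self):
        n = required_sample_size(0.91)
        assert paired_t_power(n, 0.91) >= 0.90 > paired_t_power(n - 1, 0.91)


class TestAssumptionChecks:
    def test_normal_sample_passes(self, rng):
        table = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        res = normality_and_variance_checks(table)
        assert all(v["p"] > 0.01 for v in res["shapiro"].values())
        assert res["levene"]["p"] > 0.01

    def test_constant_column_errors(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="constant"):
            normality_and_variance_checks(table)
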