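"""Tests of the statistical battery against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tva_arousal.stats_pipeline import (
    analyze_cohort,
    bh_fdr,
    chi_square_independence,
    cohens_f2,
    distribution_nonoverlap,
    effect_size_r,
    mediate,
    nested_model_f_test,
    ols_regression,
    spearman_matrix,
    wilcoxon_rank_sum,
)
from tva_arousal.synthetic_data import CohortConfig, simulate_cohort


def exact_rank_sum_p(x, y, alternative):
    """Brute-force permutation oracle for the rank-sum test (n <= 10)."""
    combined = np.concatenate([x, y])
    n, n1 = combined.size, len(x)
    ranks = sps.rankdata(combined)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(n), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.array(us)
    if alternative == "less":
        return np.mean(us <= u_obs)
    if alternative == "greater":
        return np.mean(us >= u_obs)
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


class TestWilcoxonRankSum:
    def test_identical_samples_null_result(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = rng.permutation(x)
        res = wilcoxon_rank_sum(x, y)
        assert res.r < 0.05
        assert res.p > 0.9

    def test_exact_small_sample_oracle(self):
        # x = {1,2} vs y = {3,4}: every x-value below every y-value, and
        # only 1 of the C(4,2) = 6 splits is as extreme: p = 1/6
        res = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less", method="exact")
        assert res.p == pytest.approx(1 / 6)

    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_exact_matches_permutation_enumeration(self, alternative, seed):
        rng = np.random.default_rng(seed)
        for n1, n2 in [(2, 3), (4, 4), (5, 5), (3, 7)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = wilcoxon_rank_sum(x, y, alternative=alternative, method="exact")
            assert res.p == pytest.approx(exact_rank_sum_p(x, y, alternative))

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = rng.normal(0.8, size=20)
        exact = wilcoxon_rank_sum(x, y, alternative="less", method="exact").p
        approx = wilcoxon_rank_sum(x, y, alternative="less").p
        assert approx == pytest.approx(exact, abs=0.01)

    def test_printed_statistic_reproduction(self):
        # a z of -3.03 in a sample of 80 prints as a medium effect r = 0.34
        assert round(effect_size_r(-3.03, 80), 2) == 0.34
        assert round(effect_size_r(-6.90, 80), 2) == 0.77
        assert round(effect_size_r(-4.72, 80), 2) == 0.53
        assert effect_size_r(0.0, 10) == 0.0

    def test_all_tied_degenerate(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert res.degenerate
        assert res.z == 0 and res.r == 0 and res.p == 1

    def test_ties_use_midranks_and_corrected_variance(self):
        x = [1, 2, 2, 3]
        y = [2, 3, 3, 4]
        ours = wilcoxon_rank_sum(x, y, alternative="two-sided")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.W == ref.statistic
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestChiSquare:
    def test_sex_ratio_contingency(self):
        # female/male counts 26/14 vs 32/8 give the Pearson statistic 2.257
        chi2, p, dof = chi_square_independence([[26, 14], [32, 8]])
        assert chi2 == pytest.approx(2.257, abs=5e-4)
        assert dof == 1
        assert p > 0.1

    def test_independence_gives_zero(self):
        chi2, p, _ = chi_square_independence([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)


class TestDistributionNonoverlap:
    def test_same_distribution_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        res = distribution_nonoverlap(x, y, n_boot=60, seed=0)
        assert res["nonoverlap"] < 0.1

    def test_disjoint_supports_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, size=100)
        y = rng.normal(20, 1, size=100)
        res = distribution_nonoverlap(x, y, n_boot=50, seed=0)
        assert res["nonoverlap"] > 0.95

    def test_closed_form_normal_overlap_oracle(self):
        # N(0,1) vs N(1,1): OVL = 2*Phi(-1/2), non-overlap = 1 - OVL ~ 0.383
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=5000)
        y = rng.normal(1, 1, size=5000)
        res = distribution_nonoverlap(x, y, n_boot=50, seed=0)
        truth = 1 - 2 * sps.norm.cdf(-0.5)
        assert res["nonoverlap"] == pytest.approx(truth, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            distribution_nonoverlap([1] * 10, [1, 2, 3, 4, 5], n_boot=5)


class TestSpearmanAndFdr:
    def test_matrix_trivials_and_oracle(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0, 5.0],
                "b": [10.0, 8.0, 6.0, 4.0, 2.0],
                "c": [2.0, 1.0, 4.0, 3.0, 5.0],
            }
        )
        rep = spearman_matrix(df)
        assert rep.rho.loc["a", "a"] == 1.0
        assert rep.rho.loc["a", "b"] == pytest.approx(-1.0)
        # oracle: rank both variables, then Pearson correlation of the ranks
        ra = sps.rankdata(df["a"])
        rc = sps.rankdata(df["c"])
        assert rep.rho.loc["a", "c"] == pytest.approx(np.corrcoef(ra, rc)[0, 1])
        pd.testing.assert_frame_equal(rep.rho, rep.rho.T)
        assert (rep.p_adjusted.values[~np.isnan(rep.p_adjusted.values)] >=
                np.nan_to_num(rep.p_raw.values[~np.isnan(rep.p_adjusted.values)])).all()

    def test_constant_variable_flagged_missing(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        rep = spearman_matrix(df)
        assert math.isnan(rep.rho.loc["a", "b"])
        assert not rep.significant.loc["a", "b"]

    def test_bh_stepup_hand_computation(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])
        assert rej.all()

    def test_bh_trivials(self):
        adj, _ = bh_fdr([0.03])
        assert adj[0] == 0.03
        adj, _ = bh_fdr([0.02, 0.02, 0.02, 0.02])
        np.testing.assert_allclose(adj, 0.02)

    def test_bh_order_invariant_deterministic_monotone(self):
        p = np.array([0.04, 0.001, 0.3, 0.01, 0.8])
        adj, _ = bh_fdr(p)
        perm = np.array([3, 0, 4, 1, 2])
        adj_perm, _ = bh_fdr(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])
        adj_again, _ = bh_fdr(p)
        np.testing.assert_array_equal(adj_again, adj)
        # adjusted values never fall below raw and keep the sorted order
        assert (adj >= p).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRegression:
    def test_univariate_beta_equals_pearson_r(self, rng):
        x = rng.normal(size=60)
        y = 0.6 * x + rng.normal(size=60)
        df = pd.DataFrame({"x": x, "y": y})
        res = ols_regression(df, "y", ["x"], n_boot=50, seed=0)
        assert res.beta["x"] == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-9)

    def test_noiseless_plane_recovered_exactly(self, rng):
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": 2 * x1 - x2})
        res = ols_regression(df, "y", ["x1", "x2"], n_boot=20, seed=0)
        assert res.b["x1"] == pytest.approx(2.0, abs=1e-9)
        assert res.b["x2"] == pytest.approx(-1.0, abs=1e-9)
        assert res.R2 == pytest.approx(1.0)

    def test_f2_from_printed_adjusted_r2(self):
        # the study's model 1: adjusted R^2 = 0.338 prints f^2 = 0.51
        assert round(cohens_f2(0.338), 2) == 0.51
        assert cohens_f2(0.0) == 0.0
        assert cohens_f2(0.5) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            cohens_f2(1.0)

    def test_bootstrap_ci_reproducible_and_covers_estimate(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": y})
        a = ols_regression(df, "y", ["x"], n_boot=200, seed=5)
        b = ols_regression(df, "y", ["x"], n_boot=200, seed=5)
        assert a.b_ci == b.b_ci
        lo, hi = a.b_ci["x"]
        assert lo <= a.b["x"] <= hi

    def test_rank_deficient_design_names_column(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=30)})
        with pytest.raises(ValueError, match="x2"):
            ols_regression(df, "y", ["x", "x2"], n_boot=10, seed=0)


class TestNestedModels:
    def test_rss_oracle_on_toy_data(self, rng):
        n = 12
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "y": rng.normal(size=n),
            }
        )
        red = ols_regression(df, "y", ["x1"], n_boot=10, seed=0)
        full = ols_regression(df, "y", ["x1", "x2"], n_boot=10, seed=0)
        F, (dfn, dfd), p = nested_model_f_test(red, full)
        # residual-sum-of-squares oracle via direct least squares
        X1 = np.column_stack([np.ones(n), df["x1"]])
        X2 = np.column_stack([np.ones(n), df["x1"], df["x2"]])
        rss = lambda X: np.sum(
            (df["y"] - X @ np.linalg.lstsq(X, df["y"], rcond=None)[0]) ** 2
        )
        F_oracle = ((rss(X1) - rss(X2)) / 1) / (rss(X2) / (n - 3))
        assert (dfn, dfd) == (1, 9)
        assert F == pytest.approx(F_oracle, rel=1e-9)
        assert p == pytest.approx(float(sps.f.sf(F_oracle, 1, 9)), rel=1e-9)

    def test_explained_outcome_adds_nothing(self, rng):
        x1 = rng.normal(size=40)
        df = pd.DataFrame({"x1": x1, "x2": rng.normal(size=40), "y": 3 * x1})
        red = ols_regression(df, "y", ["x1"], n_boot=10, seed=0)
        full = ols_regression(df, "y", ["x1", "x2"], n_boot=10, seed=0)
        F, _, p = nested_model_f_test(red, full)
        assert F == pytest.approx(0.0, abs=1e-9)

    def test_non_nested_rejected(self, rng):
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=20),
                "x2": rng.normal(size=20),
                "y": rng.normal(size=20),
            }
        )
        a = ols_regression(df, "y", ["x1"], n_boot=10, seed=0)
        b = ols_regression(df, "y", ["x2"], n_boot=10, seed=0)
        with pytest.raises(ValueError, match="nested"):
            nested_model_f_test(a, b)


class TestMediation:
    def test_noiseless_outcome_chain(self, rng):
        # M carries all of X's effect: Y = 3M exactly, M ~ 2X, so the
        # direct path is exactly zero and the indirect effect is ~6
        x = rng.normal(size=50)
        m = 2 * x + rng.normal(0, 0.01, size=50)
        df = pd.DataFrame({"x": x, "m": m, "y": 3 * m})
        res = mediate(df, "x", "m", "y", n_boot=50, seed=0)
        assert res.direct == pytest.approx(0.0, abs=1e-8)
        assert res.indirect == pytest.approx(6.0, abs=0.05)
        assert res.indirect == pytest.approx(res.total, abs=1e-8)

    def test_total_equals_direct_plus_indirect(self, rng):
        df = pd.DataFrame(
            {
                "x": rng.normal(size=80),
                "m": rng.normal(size=80),
                "y": rng.normal(size=80),
            }
        )
        res = mediate(df, "x", "m", "y", n_boot=20, seed=0)
        assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-8)

    def test_null_calibration(self):
        # independent X, M, Y: the indirect CI should cover 0 nearly always
        covered = 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            df = pd.DataFrame(
                {
                    "x": rng.normal(size=200),
                    "m": rng.normal(size=200),
                    "y": rng.normal(size=200),
                }
            )
            r = mediate(df, "x", "m", "y", n_boot=300, seed=s)
            covered += r.indirect_ci[0] <= 0 <= r.indirect_ci[1]
        assert covered / n_rep >= 0.90

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 12, "m": range(12), "y": range(12)})
        with pytest.raises(ValueError, match="zero variance"):
            mediate(df, "x", "m", "y", n_boot=10)


class TestAnalyzeCohort:
    def test_fatigue_effect_large_in_calibrated_cohorts(self):
        # at the configured group separation the mental-fatigue rank test
        # should be a large effect (r > 0.5) in nearly every replicate
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            df = simulate_cohort(CohortConfig(n_per_group=40), seed=3000 + s)
            pat = df[df["group"] == "patient"]
            con = df[df["group"] == "control"]
            res = wilcoxon_rank_sum(
                con["fatigue_mental"], pat["fatigue_mental"], alternative="less"
            )
            hits += res.r > 0.5
        assert hits / n_rep >= 0.95

    def test_full_battery_report_structure(self):
        df = simulate_cohort(CohortConfig(n_per_group=40), seed=17)
        rep = analyze_cohort(df, n_boot=100, seed=17)
        assert set(rep["group_tests"]) >= {"C", "K", "t0", "fatigue_mental"}
        assert rep["regression"]["model1"]["n"] == 40
        assert 0 <= rep["regression"]["model1"]["R2_adj"] <= 1
        assert rep["mediation"]["total"] == pytest.approx(
            rep["mediation"]["direct"] + rep["mediation"]["indirect"], abs=1e-8
        )
        assert rep["nonoverlap"].keys() == {"C", "K", "t0"}
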