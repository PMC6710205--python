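"""Group tests, covariate separation, correlations, regression lines."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from dvrphys.stats import (
    DegenerateVarianceError,
    chi2_2x2,
    correlation_matrix,
    covariate_adjust,
    group_table,
    pearson,
    simple_regression,
    welch_t,
)
from dvrphys.synthetic import CohortSpec, generate_cohort


# Printed group summaries (mean, SD, n per group) and the p-value each
# reproduces under the Welch unequal-variance t-test.
PRINTED_ROWS = [
    ("DVR", 1.1546, 0.6461, 16, 0.5449, 0.6031, 36, 0.0034),
    ("FA", 0.5950, 0.0283, 16, 0.5772, 0.0327, 36, 0.0546),
    ("Trails-B", 56.9375, 15.0575, 16, 77.1389, 30.9222, 36, 0.0027),
    ("WAIS-dig", 7.3125, 1.8154, 16, 5.7500, 1.9030, 36, 0.0084),
    ("CVLT-LDFR", 12.0000, 2.5298, 16, 9.4444, 2.3354, 36, 0.0019),
    ("CVLT-total", 53.3750, 10.0391, 16, 45.2778, 11.2596, 36, 0.0145),
    ("LF-F&A&S", 39.6875, 7.5694, 16, 36.3056, 11.2016, 36, 0.2104),
    ("DVR-adjusted", 1.1546, 0.5789, 16, 0.5457, 0.5825, 36, 0.0015),
    ("RD-adjusted", 0.4627, 0.0198, 16, 0.4876, 0.0270, 36, 0.0006),
]


class TestWelch:
    @pytest.mark.parametrize(
        "name,m1,s1,n1,m2,s2,n2,expected",
        PRINTED_ROWS, ids=[r[0] for r in PRINTED_ROWS])
    def test_reproduces_printed_group_pvalues(self, name, m1, s1, n1, m2, s2,
                                              n2, expected):
        assert welch_t(m1, s1, n1, m2, s2, n2).p == pytest.approx(
            expected, abs=5e-4)

    def test_equal_means_give_t_zero_p_one(self):
        res = welch_t(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_vector_form_equals_summary_form(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 2, 30)
        from_vec = welch_t(x, y)
        from_sum = welch_t(x.mean(), x.std(ddof=1), 25,
                           y.mean(), y.std(ddof=1), 30)
        assert from_vec.p == pytest.approx(from_sum.p, abs=1e-12)
        assert from_vec.df == pytest.approx(from_sum.df, abs=1e-9)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            welch_t(1.0, 0.0, 10, 2.0, 0.0, 10)

    def test_pvalue_matches_quadrature_oracle(self):
        # independent check of the t tail probability by adaptive
        # quadrature of the density
        res = welch_t(1.1546, 0.6461, 16, 0.5449, 0.6031, 36)
        dens = lambda u: sps.t.pdf(u, res.df)
        tail, _ = integrate.quad(dens, abs(res.statistic), np.inf)
        assert res.p == pytest.approx(2 * tail, abs=1e-8)

    def test_type_one_error_calibration(self, rng):
        n_rep, alpha = 10_000, 0.05
        x = rng.normal(0, 1, (n_rep, 16))
        y = rng.normal(0, 1, (n_rep, 36))
        rej = sum(welch_t(x[i].mean(), x[i].std(ddof=1), 16,
                          y[i].mean(), y[i].std(ddof=1), 36).p < alpha
                  for i in range(n_rep))
        assert 0.04 <= rej / n_rep <= 0.06


class TestChi2:
    @pytest.mark.parametrize("a,b,c,d,expected", [
        (9, 7, 14, 22, 0.245),   # antihypertensive use, controls vs MCI
        (7, 9, 8, 28, 0.114),    # cholesterol medication
    ])
    def test_reproduces_printed_medication_pvalues(self, a, b, c, d, expected):
        assert chi2_2x2(a, b, c, d).p == pytest.approx(expected, abs=1e-3)

    def test_proportional_rows_give_zero_statistic(self):
        res = chi2_2x2(10, 20, 5, 10)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2(0, 0, 5, 10)

    def test_matches_scipy_contingency(self):
        oracle = sps.chi2_contingency([[9, 7], [14, 22]], correction=False)
        res = chi2_2x2(9, 7, 14, 22)
        assert res.statistic == pytest.approx(oracle.statistic, abs=1e-12)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-12)


class TestCovariateAdjust:
    def test_residuals_orthogonal_to_covariates(self, cohort):
        adj = covariate_adjust(cohort, "DVR")
        resid = adj - adj.mean()
        for cov in ("age", "gender", "education"):
            c = cohort[cov] - cohort[cov].mean()
            scale = np.linalg.norm(resid) * np.linalg.norm(c)
            assert abs(np.dot(resid, c)) < 1e-8 * scale

    def test_control_group_mean_preserved(self, cohort):
        adj = covariate_adjust(cohort, "DVR")
        cs = cohort["group"] == "CS"
        assert adj[cs].mean() == pytest.approx(cohort.loc[cs, "DVR"].mean(),
                                               abs=1e-10)

    def test_null_covariates_change_little_at_large_n(self):
        tab = generate_cohort(CohortSpec(n_cs=3000, n_mp=3000, seed=9))
        adj = covariate_adjust(tab, "DVR")
        # covariates are generated independent of markers: adjustment is
        # a near-identity up to recentring
        assert np.corrcoef(adj, tab["DVR"])[0, 1] > 0.999

    def test_constructed_confound_is_removed(self, rng):
        n = 400
        age = rng.normal(65, 7, n)
        group = np.where(np.arange(n) < n // 2, "CS", "MP")
        signal = np.where(group == "CS", 1.0, 0.4)
        tab = pd.DataFrame({
            "group": group, "age": age,
            "gender": rng.integers(0, 2, n),
            "education": rng.normal(16, 2, n),
            "marker": signal + 0.1 * age + rng.normal(0, 0.3, n)})
        adj = covariate_adjust(tab, "marker")
        diff = adj[group == "CS"].mean() - adj[group == "MP"].mean()
        assert diff == pytest.approx(0.6, abs=0.12)

    def test_collinear_covariates_rejected(self, cohort):
        tab = cohort.copy()
        tab["age2"] = 2 * tab["age"]
        with pytest.raises(ValueError, match="collinear"):
            covariate_adjust(tab, "DVR", covariates=["age", "age2"])


class TestPearson:
    def test_self_correlation(self, rng):
        x = rng.normal(0, 1, 50)
        assert pearson(x, x).estimate == pytest.approx(1.0)
        assert pearson(x, -x).estimate == pytest.approx(-1.0)

    def test_population_r_recovered_in_large_sample(self, rng):
        r_target = 0.6107
        z = rng.multivariate_normal(
            [0, 0], [[1, r_target], [r_target, 1]], size=1000)
        res = pearson(z[:, 0], z[:, 1])
        assert res.estimate == pytest.approx(r_target, abs=0.05)
        assert res.p < 0.001

    def test_pairwise_complete_deletion(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 0.5, 30)
        x_miss = x.copy()
        x_miss[[3, 7]] = np.nan
        res = pearson(x_miss, y)
        assert res.n == 28

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            pearson(np.ones(10), np.arange(10.0))


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = simple_regression(x, 2 * x + 1)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["intercept"] == pytest.approx(1.0)
        assert fit["r2"] == pytest.approx(1.0)

    def test_five_point_hand_computation(self):
        # x=[1..5], y=[2,1,4,3,7]: deviation products sum to 12.0 so
        # cov=3.0, var(x)=2.5 -> slope=1.2, intercept=3.4-1.2*3=-0.2
        fit = simple_regression([1, 2, 3, 4, 5], [2, 1, 4, 3, 7])
        assert fit["slope"] == pytest.approx(1.2)
        assert fit["intercept"] == pytest.approx(-0.2)

    def test_recovers_generating_line(self, rng):
        # FA generated from DVR along the line FA = 0.025*DVR + 0.564
        dvr = rng.normal(0.85, 0.65, 2000)
        fa = 0.025 * dvr + 0.564 + rng.normal(0, 0.02, 2000)
        fit = simple_regression(dvr, fa)
        se = 0.02 / (dvr.std() * np.sqrt(2000))
        assert fit["slope"] == pytest.approx(0.025, abs=3 * se)
        assert fit["intercept"] == pytest.approx(0.564, abs=0.005)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            simple_regression(np.ones(5), np.arange(5.0))


class TestGroupTable:
    def test_shape_and_columns(self, cohort):
        gt = group_table(cohort)
        assert len(gt) == 11
        for col in ("mean_CS", "sd_CS", "mean_MP", "sd_MP", "p",
                    "mean_CS_adj", "p_adj", "sig_05", "sig_01"):
            assert col in gt.columns

    def test_adjusted_control_means_equal_unadjusted(self, cohort):
        gt = group_table(cohort)
        np.testing.assert_allclose(gt["mean_CS"], gt["mean_CS_adj"],
                                   atol=1e-10)

    def test_default_cohort_separates_about_six_of_eleven(self):
        counts = [
            (group_table(generate_cohort(CohortSpec(seed=s)))["p"] < 0.01).sum()
            for s in range(15)]
        assert 5 <= np.median(counts) <= 8

    def test_null_cohort_false_positive_rate(self):
        moments = {g: [(10.0, 2.0)] * 4 for g in ("CS", "MP")}
        spec_kw = dict(markers=["m1", "m2", "m3", "m4"],
                       moments=moments, correlation=np.eye(4))
        hits = total = 0
        for seed in range(100):
            gt = group_table(generate_cohort(CohortSpec(seed=seed, **spec_kw)))
            hits += (gt["p"] < 0.05).sum()
            total += len(gt)
        assert 0.02 < hits / total < 0.09

    def test_single_subject_group_rejected(self, cohort):
        tiny = pd.concat([cohort[cohort.group == "CS"].iloc[:1],
                          cohort[cohort.group == "MP"]])
        with pytest.raises(ValueError, match="fewer than 2"):
            group_table(tiny)

    def test_variable_missing_in_one_group_flagged(self, cohort):
        tab = cohort.copy()
        tab.loc[tab.group == "CS", "VRT"] = np.nan
        gt = group_table(tab)
        assert np.isnan(gt.loc["VRT", "p"])
        assert gt.loc["VRT", "note"] != ""


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_correlation(self, cohort):
        tab = cohort.copy()
        tab["DVR2"] = tab["DVR"]
        cm = correlation_matrix(tab, ["DVR", "DVR2", "FA"])
        assert cm[("r", "DVR2")]["DVR"] == pytest.approx(1.0)

    def test_symmetric_with_unit_diagonal(self, cohort):
        cm = correlation_matrix(cohort, ["DVR", "FA", "MD"])
        r = cm["r"].to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_null_column_p_uniform(self, rng):
        # p-values of an independent column should be uniform on (0,1)
        ps = []
        for _ in range(200):
            x = rng.normal(0, 1, 52)
            y = rng.normal(0, 1, 52)
            ps.append(pearson(x, y).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_cell_does_not_abort_matrix(self, cohort):
        tab = cohort.copy()
        tab["const"] = 1.0
        cm = correlation_matrix(tab, ["DVR", "FA", "const"])
        assert np.isnan(cm[("r", "const")]["DVR"])
        assert cm[("r", "FA")]["DVR"] == pytest.approx(
            pearson(tab["DVR"], tab["FA"]).estimate)

    def test_matrix_close_to_targets_at_large_n(self):
        tab = generate_cohort(CohortSpec(n_cs=2500, n_mp=2500, seed=17))
        cm = correlation_matrix(tab, ["DVR", "FA", "MD", "RD"])
        assert cm[("r", "FA")]["DVR"] == pytest.approx(0.6107, abs=0.04)
        assert cm[("r", "MD")]["DVR"] == pytest.approx(-0.6197, abs=0.04)
        assert cm[("r", "RD")]["FA"] == pytest.approx(-0.8188, abs=0.04)
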