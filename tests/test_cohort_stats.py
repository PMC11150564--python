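"""Group comparisons, GLM with VIF screen, and correlation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dtialps.cohort import (
    chi_square_2x2,
    fit_alps_glm,
    mann_whitney_u,
    partial_corr,
    shapiro_wilk,
    spearman_corr,
    table1_report,
    two_sample_t,
    two_sample_t_from_summary,
)
from dtialps.exceptions import ValidationError
from dtialps.synthetic import simulate_cohort, table1_fixture


class TestShapiroWilk:
    def test_gaussian_samples_usually_pass(self):
        rng = np.random.default_rng(0)
        passes = sum(
            shapiro_wilk(rng.standard_normal(50)).p > 0.05 for _ in range(100)
        )
        assert passes >= 90

    def test_lognormal_samples_usually_fail(self):
        rng = np.random.default_rng(1)
        fails = sum(
            shapiro_wilk(np.exp(rng.standard_normal(50))).p < 0.05
            for _ in range(100)
        )
        assert fails >= 90

    def test_n_below_three_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([3.0] * 10)


class TestTwoSampleT:
    def test_equal_means_give_t_zero_p_one(self):
        res = two_sample_t_from_summary(5.0, 1.0, 10, 5.0, 1.2, 12)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_summary_path_matches_scipy_from_stats(self):
        res = two_sample_t_from_summary(25.48, 3.09, 41, 23.60, 3.22, 27)
        t_ref, p_ref = stats.ttest_ind_from_stats(
            25.48, 3.09, 41, 23.60, 3.22, 27, equal_var=True
        )
        assert res.statistic == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)
        assert res.df == 66

    def test_welch_matches_scipy(self):
        res = two_sample_t_from_summary(4.72, 0.95, 41, 5.01, 0.92, 27, "welch")
        t_ref, p_ref = stats.ttest_ind_from_stats(
            4.72, 0.95, 41, 5.01, 0.92, 27, equal_var=False
        )
        assert res.statistic == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)

    def test_raw_and_summary_paths_agree_algebraically(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(5, 40))
            b = rng.normal(0.3, 1.5, rng.integers(5, 40))
            raw = two_sample_t(a, b)
            summ = two_sample_t_from_summary(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
            )
            assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
            assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_bmi_pvalue_consistent_with_printed_summary_rounding(self):
        # group summaries are printed to 2 decimals; half-ULP propagation puts
        # the admissible pooled-t p in [0.0176, 0.0196] around the exact 0.0185
        res = two_sample_t_from_summary(25.48, 3.09, 41, 23.60, 3.22, 27)
        assert res.p == pytest.approx(0.018546, abs=5e-5)
        lo = two_sample_t_from_summary(25.485, 3.095, 41, 23.595, 3.215, 27).p
        hi = two_sample_t_from_summary(25.475, 3.085, 41, 23.605, 3.225, 27).p
        assert lo < 0.018 < hi or lo < res.p < hi

    def test_identical_groups_give_p_one(self):
        x = np.arange(10.0)
        assert two_sample_t(x, x).p == pytest.approx(1.0)

    def test_cohort_effect_rejection_rate_matches_power_oracle(self):
        # ALPS 1.30+/-0.13 (n=41) vs 1.44+/-0.11 (n=27): exact noncentral-t
        # power at two-sided alpha=0.001 is 0.871; the empirical rate must sit
        # in the binomial 99% band around it (alpha=0.05 power is ~0.995)
        sp2 = (40 * 0.13**2 + 26 * 0.11**2) / 66
        se = np.sqrt(sp2 * (1 / 41 + 1 / 27))
        ncp = 0.14 / se
        crit = stats.t.ppf(1 - 0.0005, 66)
        power = stats.nct.sf(crit, 66, ncp) + stats.nct.cdf(-crit, 66, ncp)
        n_rep = 100
        hits = 0
        for s in range(n_rep):
            df = simulate_cohort(seed=30_000 + s)
            g = df["group"].astype(str)
            p = two_sample_t(df.loc[g == "T2DM", "alps"], df.loc[g == "HC", "alps"]).p
            hits += p < 0.001
        band = 2.58 * np.sqrt(power * (1 - power) / n_rep)
        assert abs(hits / n_rep - power) < band + 0.01


class TestMannWhitney:
    def test_fully_separated_small_groups_exact(self):
        # all 20 assignments of {1..6} into 3+3: only 2 are this extreme
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_small_samples_use_exact_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 6)
            exact = stats.mannwhitneyu(a, b, method="exact").pvalue
            assert mann_whitney_u(a, b).p == pytest.approx(exact, abs=1e-12)

    def test_asymptotic_approaches_exact_at_moderate_n(self):
        # the normal approximation is coarse at n=6+6 (errors up to ~0.06 in
        # the mid-p range); at n=20+20 it tracks the enumeration within 0.02
        rng = np.random.default_rng(30)
        for _ in range(10):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0.5, 1, 20)
            exact = stats.mannwhitneyu(a, b, method="exact").pvalue
            assert mann_whitney_u(a, b).p == pytest.approx(exact, abs=0.02)


class TestChiSquare:
    def test_table1_sex_counts(self):
        res = chi_square_2x2(20, 21, 17, 10)
        assert res.statistic == pytest.approx(1.320, abs=1e-3)
        assert res.p == pytest.approx(0.251, abs=1e-3)

    def test_proportional_table_gives_zero(self):
        res = chi_square_2x2(10, 10, 5, 5)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_expected_counts(self):
        # margins 41/27 and 37/31 -> expected 22.309/18.691/14.691/12.309
        res = chi_square_2x2(20, 21, 17, 10)
        e = np.array([22.309, 18.691, 14.691, 12.309])
        o = np.array([20, 21, 17, 10])
        assert res.statistic == pytest.approx(((o - e) ** 2 / e).sum(), abs=1e-3)

    @pytest.mark.parametrize("k", [2, 5])
    def test_count_scaling_multiplies_statistic(self, k):
        base = chi_square_2x2(20, 21, 17, 10)
        scaled = chi_square_2x2(20 * k, 21 * k, 17 * k, 10 * k)
        assert scaled.statistic == pytest.approx(k * base.statistic, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2(0, 0, 5, 5)


def _orthogonal_cohort(n=24, seed=4):
    """Cohort whose 8 covariates are exactly orthogonal (and zero-mean bar sex)."""
    rng = np.random.default_rng(seed)
    sex = np.tile([0.0, 1.0], n // 2)  # balanced within each group
    base = np.column_stack([np.ones(n), sex - sex.mean()])
    raw = rng.standard_normal((n, 7))
    # orthogonalize against intercept+sex and each other
    q, _ = np.linalg.qr(np.column_stack([base, raw]))
    covs = q[:, 2:9]
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["T2DM"] * (n // 2) + ["HC"] * (n // 2),
            "sex": sex,
            "alps": rng.normal(1.4, 0.1, n),
        }
    )
    for name, col in zip(
        ("age", "education_years", "BMI", "triglyceride", "cholesterol", "LDL", "HDL"),
        covs.T,
    ):
        df[name] = col
    return df


class TestAlpsGlm:
    def test_known_group_effect_coverage(self):
        hits = 0
        for s in range(100):
            df = simulate_cohort(seed=40_000 + s)
            g = fit_alps_glm(df)
            lo = g.group_effect - 1.96 * g.group_se
            hi = g.group_effect + 1.96 * g.group_se
            hits += lo <= -0.14 <= hi
        assert hits >= 93

    def test_orthogonal_covariates_have_unit_vif(self):
        g = fit_alps_glm(_orthogonal_cohort())
        np.testing.assert_allclose(g.vif.to_numpy(), 1.0, atol=1e-8)

    def test_duplicated_covariate_is_rank_deficiency_error(self):
        df = _orthogonal_cohort()
        df["LDL"] = df["cholesterol"]
        with pytest.raises(ValidationError, match="rank"):
            fit_alps_glm(df)

    def test_too_few_complete_cases_rejected(self):
        df = _orthogonal_cohort(n=24)
        df.loc[df.index[:14], "BMI"] = np.nan
        with pytest.raises(ValidationError, match="complete"):
            fit_alps_glm(df)

    def test_vif_detects_injected_collinearity(self):
        df = _orthogonal_cohort()
        rng = np.random.default_rng(5)
        df["LDL"] = 0.98 * df["cholesterol"] + 0.02 * rng.standard_normal(len(df))
        g = fit_alps_glm(df)
        assert g.vif["LDL"] > 5.0 and g.vif["cholesterol"] > 5.0
        assert g.vif["BMI"] < 2.0


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        res = spearman_corr(x, np.exp(x))
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_reversal_gives_minus_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        assert spearman_corr(x, -x).r == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.integers(0, 10, 30).astype(float)  # ties likely
            y = x + rng.normal(0, 3, 30)
            ours = spearman_corr(x, y)
            ref = stats.spearmanr(x, y)
            assert ours.r == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialCorr:
    def test_controlling_the_driver_kills_the_correlation(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(500)
        x = rng.standard_normal(500)
        res = partial_corr(x, z, z, rank_based=False)
        assert abs(res.r) < 0.05

    def test_no_covariates_reduces_to_spearman(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        pc = partial_corr(x, y, np.empty((40, 0)), rank_based=True)
        sp = spearman_corr(x, y)
        assert pc.r == pytest.approx(sp.r, abs=1e-12)
        assert pc.p == pytest.approx(sp.p, abs=1e-12)

    def test_shared_covariate_removal_leaves_identity(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(60)
        e = rng.standard_normal(60)
        x = 2.0 * z + e
        y = -1.0 * z + e  # identical residual after removing z
        res = partial_corr(x, y, z, rank_based=False)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal(30)
        with pytest.raises(ValidationError):
            partial_corr(
                rng.standard_normal(30),
                rng.standard_normal(30),
                np.column_stack([z, z]),
            )


class TestTable1Report:
    def test_synthetic_cohort_report_covers_all_variables(self):
        df = simulate_cohort(seed=11)
        rep = table1_report(df)
        fixture_vars = set(table1_fixture()["rows"].keys())
        assert fixture_vars <= set(rep["variable"])
        assert "sex" in set(rep["variable"])
        assert rep["p"].between(0, 1).all()

    def test_normal_variables_use_student_t(self):
        rng = np.random.default_rng(0)  # draws pass all four normality gates
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(60)],
                "group": ["T2DM"] * 30 + ["HC"] * 30,
                "age": rng.normal(60, 8, 60),
                "BMI": rng.normal(25, 3, 60),
            }
        )
        rep = table1_report(df)
        assert (rep["test_name"] == "student_t").all()

    def test_skewed_variable_falls_back_to_mann_whitney(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(80)],
                "group": ["T2DM"] * 40 + ["HC"] * 40,
                "triglyceride": np.exp(rng.standard_normal(80)),
            }
        )
        rep = table1_report(df)
        assert rep.loc[rep["variable"] == "triglyceride", "test_name"].iloc[0] == (
            "mann_whitney_u"
        )

    def test_sex_only_table_yields_single_chi_square_row(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(20)],
                "group": ["T2DM"] * 10 + ["HC"] * 10,
                "sex": ["F", "M"] * 10,
            }
        )
        rep = table1_report(df)
        assert list(rep["test_name"]) == ["chi_square"]
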