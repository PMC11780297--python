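"""Effect sizes, t tests, multiple imputation, Rubin pooling, mixed models,
feasibility arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import simulate_trajectories
from hftrialkit.instruments import ValidationError
from hftrialkit.trial_stats import (
    GroupSummary,
    change_scores,
    cohen_d_from_summary,
    feasibility_metrics,
    fit_random_intercept_lmm,
    mi_impute,
    rubin_pool,
    summarize_group,
    two_sample_t,
)


class TestChangeScores:
    def frame(self, ids, values):
        return pd.DataFrame({"patient_id": ids, "score": values})

    def test_subtraction(self):
        out = change_scores(self.frame(["a"], [70.0]), self.frame(["a"], [78.0]))
        assert out["delta"].iloc[0] == 8.0

    def test_identical_visits_zero_deltas(self):
        b = self.frame(list("abc"), [60, 70, 80])
        out = change_scores(b, b.copy())
        g = summarize_group(out["delta"])
        assert g.mean_change == 0.0 and g.sd_change == 0.0

    def test_hand_arithmetic_mean_and_sd(self):
        out = change_scores(
            self.frame(list("abc"), [0, 0, 0]), self.frame(list("abc"), [2, 4, 6])
        )
        g = summarize_group(out["delta"])
        assert g.mean_change == 4.0 and g.sd_change == pytest.approx(2.0)

    def test_unmatched_patients_excluded(self):
        out = change_scores(
            self.frame(list("ab"), [1, 2]), self.frame(list("bc"), [3, 4])
        )
        assert list(out["patient_id"]) == ["b"] and out.attrs["n_dropped"] == 2


def construct_sample(n, mean, sd, rng):
    """Sample with exactly the requested mean and (n-1)-denominator SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestEffectSizes:
    def test_antisymmetry(self):
        g1 = GroupSummary(11, 6.36, 15.34)
        g2 = GroupSummary(14, 3.75, 12.51)
        a = cohen_d_from_summary(g1, g2)
        b = cohen_d_from_summary(g2, g1)
        assert a.d == pytest.approx(-b.d)
        assert a.ci_low == pytest.approx(-b.ci_high)
        assert a.ci_high == pytest.approx(-b.ci_low)

    def test_equal_means_give_zero(self):
        r = cohen_d_from_summary(GroupSummary(5, 2.0, 3.0), GroupSummary(8, 2.0, 7.0))
        assert r.d == 0.0

    def test_zero_pooled_sd_unequal_means_undefined(self):
        with pytest.raises(ValidationError):
            cohen_d_from_summary(GroupSummary(5, 2.0, 0.0), GroupSummary(5, 3.0, 0.0))

    def test_summary_path_matches_sample_reconstruction(self):
        """d from summaries equals d recomputed from synthetic samples built
        to have exactly those means and SDs."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            n1, n2 = rng.integers(5, 30, 2)
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 10, 2)
            x1 = construct_sample(n1, m1, s1, rng)
            x2 = construct_sample(n2, m2, s2, rng)
            sp = np.sqrt(
                ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1))
                / (n1 + n2 - 2)
            )
            brute = (x1.mean() - x2.mean()) / sp
            r = cohen_d_from_summary(
                GroupSummary(int(n1), float(m1), float(s1)),
                GroupSummary(int(n2), float(m2), float(s2)),
            )
            assert r.d == pytest.approx(brute, rel=1e-9)

    def test_ci_width_shrinks_with_n(self):
        widths = [
            (lambda r: r.ci_high - r.ci_low)(
                cohen_d_from_summary(GroupSummary(n, 5.0, 10.0), GroupSummary(n, 1.0, 10.0))
            )
            for n in (5, 10, 20, 40, 80)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_normal_ci_narrower_than_t(self):
        g1, g2 = GroupSummary(11, 7.83, 9.85), GroupSummary(14, 4.37, 10.93)
        t_ci = cohen_d_from_summary(g1, g2)
        n_ci = cohen_d_from_summary(g1, g2, ci_method="normal")
        assert (n_ci.ci_high - n_ci.ci_low) < (t_ci.ci_high - t_ci.ci_low)


class TestTwoSampleT:
    def test_null_case(self):
        t, df, p = two_sample_t(GroupSummary(6, 1.0, 2.0), GroupSummary(9, 1.0, 3.0))
        assert t == 0.0 and p == 1.0 and df == 13

    def test_matches_scipy_from_stats(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n1, n2 = rng.integers(4, 25, 2)
            g1 = GroupSummary(int(n1), float(rng.normal()), float(rng.uniform(0.5, 5)))
            g2 = GroupSummary(int(n2), float(rng.normal()), float(rng.uniform(0.5, 5)))
            t, df, p = two_sample_t(g1, g2)
            ref = stats.ttest_ind_from_stats(
                g1.mean_change, g1.sd_change, g1.n,
                g2.mean_change, g2.sd_change, g2.n,
            )
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestMultipleImputation:
    def test_no_missing_cells_identity(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 6]})
        imp = mi_impute(df, ["x"], outcome_cols=["y"], m=3, seed=0)
        for d in imp.datasets:
            pd.testing.assert_frame_equal(d, df)

    def test_observed_cells_identical_across_copies(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        df.loc[::5, "y"] = np.nan
        imp = mi_impute(df, ["x"], outcome_cols=["y"], m=4, seed=2)
        obs = ~df["y"].isna()
        for d in imp.datasets:
            assert np.allclose(d.loc[obs, "y"], df.loc[obs, "y"])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        df.loc[::4, "y"] = np.nan
        a = mi_impute(df, ["x"], outcome_cols=["y"], m=3, seed=9)
        b = mi_impute(df, ["x"], outcome_cols=["y"], m=3, seed=9)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_collinear_predictor_recovers_deterministic_fit(self):
        """With y = 2x exactly in complete cases, the regression residual is
        zero and every imputation equals the closed-form fit."""
        x = np.arange(10, dtype=float)
        y = 2 * x
        y[7] = np.nan
        df = pd.DataFrame({"x": x, "y": y})
        imp = mi_impute(df, ["x"], outcome_cols=["y"], m=5, seed=0)
        for d in imp.datasets:
            assert d["y"].iloc[7] == pytest.approx(14.0, abs=1e-6)

    def test_overly_missing_column_refused(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": [1.0] + [np.nan] * 9})
        with pytest.raises(ValidationError):
            mi_impute(df, ["x"], outcome_cols=["y"], m=2, seed=0)

    def test_pmm_draws_observed_values_only(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)})
        df.loc[::3, "y"] = np.nan
        imp = mi_impute(df, ["x"], outcome_cols=["y"], m=3, seed=1, method="pmm")
        observed = set(df["y"].dropna())
        for d in imp.datasets:
            assert set(d.loc[df["y"].isna(), "y"]) <= observed


class TestRubinPooling:
    def test_hand_computed_example(self):
        pooled, se = rubin_pool([1, 2, 3], [1, 1, 1])
        assert pooled == 2.0
        assert se == pytest.approx(np.sqrt(1 + (4 / 3) * 1.0))

    def test_identical_estimates_degenerate_between_variance(self):
        pooled, se = rubin_pool([5.0] * 6, [2.0] * 6)
        assert pooled == 5.0 and se == pytest.approx(np.sqrt(2.0))

    def test_zero_within_variance_limit(self):
        est = list(np.arange(20, dtype=float))
        _, se = rubin_pool(est, [0.0] * 20)
        assert se == pytest.approx(np.sqrt((21 / 20) * np.var(est, ddof=1)))

    def test_large_m_converges_to_sample_variance_identity(self):
        rng = np.random.default_rng(0)
        q = rng.normal(3.0, 1.0, 10_000)
        u = np.full(10_000, 0.5)
        pooled, se = rubin_pool(q, u)
        assert pooled == pytest.approx(q.mean())
        assert se**2 == pytest.approx(0.5 + np.var(q, ddof=1), rel=1e-3)

    def test_single_estimate_rejected(self):
        with pytest.raises(ValidationError):
            rubin_pool([1.0], [1.0])


class TestMixedModel:
    def test_perfect_line_zero_variances(self):
        rows = [
            {"patient_id": f"s{s}", "week": w, "y": 90.0 - 1.0 * w}
            for s in range(5)
            for w in range(1, 9)
        ]
        fit = fit_random_intercept_lmm(pd.DataFrame(rows))
        assert fit.slope == pytest.approx(-1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(90.0, abs=1e-9)
        assert fit.residual_var == 0.0

    def test_one_observation_per_subject_pins_variance(self):
        rng = np.random.default_rng(2)
        rows = [
            {"patient_id": f"s{s}", "week": s % 8 + 1, "y": float(rng.normal(50, 5))}
            for s in range(12)
        ]
        with pytest.warns(UserWarning):
            fit = fit_random_intercept_lmm(pd.DataFrame(rows))
        assert fit.random_intercept_var == 0.0

    def test_degenerate_path_agrees_with_ols(self):
        """With the random intercept pinned at zero the fit is exactly OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        rows = [
            {"patient_id": f"s{s}", "week": s % 8 + 1, "y": float(rng.normal(50, 5))}
            for s in range(12)
        ]
        df = pd.DataFrame(rows)
        with pytest.warns(UserWarning):
            fit = fit_random_intercept_lmm(df)
        ols = sm.OLS(df["y"], sm.add_constant(df["week"].astype(float))).fit()
        assert fit.intercept == pytest.approx(ols.params.iloc[0], abs=1e-6)
        assert fit.slope == pytest.approx(ols.params.iloc[1], abs=1e-6)

    def test_df_convention(self):
        df = simulate_trajectories(0)
        fit = fit_random_intercept_lmm(df)
        assert fit.df == 88 - 11 - 1
        fit2 = fit_random_intercept_lmm(df, df_method="residual")
        assert fit2.df == 86

    def test_recovers_known_parameters_roughly(self):
        df = simulate_trajectories(42)
        fit = fit_random_intercept_lmm(df)
        assert fit.slope == pytest.approx(-0.95, abs=1.5)
        assert fit.random_intercept_var > 0


class TestFeasibility:
    def log(self, n_screened=504, n_eligible=79, n_enrolled=29, n_randomized=27,
            n_analyzable=25):
        return pd.DataFrame(
            {
                "eligible": [i < n_eligible for i in range(n_screened)],
                "enrolled": [i < n_enrolled for i in range(n_screened)],
                "randomized": [i < n_randomized for i in range(n_screened)],
                "analyzable": [i < n_analyzable for i in range(n_screened)],
                "completed_week8": [i < n_analyzable for i in range(n_screened)],
            }
        )

    def test_recruitment_fraction(self):
        m = feasibility_metrics(self.log())
        assert m.recruitment_fraction_pct == 5.8

    def test_recruitment_rate(self):
        m = feasibility_metrics(self.log(n_enrolled=30), months=10)
        assert m.recruitment_rate_per_month == pytest.approx(3.0)

    def test_full_retention(self):
        m = feasibility_metrics(self.log())
        assert m.retention_pct["week8"] == 100.0

    def test_empty_log_rejected(self):
        with pytest.raises(ValidationError):
            feasibility_metrics(self.log(n_screened=0))
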