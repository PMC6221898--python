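"""Statistical battery: t tests, χ², interaction contrasts, partial r,
BH-FDR, stepwise regression — unit examples plus oracle equivalences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emoeeg.stats import (bh_fdr, chi_square_gof, paired_t,
                          paired_t_from_summary, partial_correlation,
                          stepwise_regression, within_interaction_multivariate,
                          within_interaction_univariate)


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t([1, 2, 3], [2, 2, 4])
        assert res.statistic == pytest.approx(-2.0)
        assert res.df == (2,)

    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_constant_nonzero_difference_flagged_infinite(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(res.statistic) and res.statistic > 0
        assert res.p == 0.0

    def test_matches_summary_reconstruction(self, rng):
        x = rng.standard_normal(33)
        y = rng.standard_normal(33)
        full = paired_t(x, y)
        d = x - y
        summary = paired_t_from_summary(d.mean(), d.std(ddof=1), 33)
        assert full.statistic == pytest.approx(summary.statistic)
        assert full.p == pytest.approx(summary.p)

    def test_reports_both_effect_size_conventions(self, rng):
        x = rng.standard_normal(20) + 0.5
        y = rng.standard_normal(20)
        res = paired_t(x, y)
        d = x - y
        assert res.extra["d_z"] == pytest.approx(d.mean() / d.std(ddof=1))
        assert res.extra["d_av"] == pytest.approx(
            d.mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2))

    def test_type_one_error_and_power_at_n33(self):
        """Null rejection rate ≈ 0.05; power ≥ 0.85 at planted d_z = 0.8."""
        rng = np.random.default_rng(2024)
        n, reps, alpha = 33, 2000, 0.05
        import scipy.stats
        null = rng.standard_normal((reps, n))
        t_null = null.mean(1) / (null.std(1, ddof=1) / np.sqrt(n))
        p_null = 2 * scipy.stats.t.sf(np.abs(t_null), n - 1)
        assert 0.03 <= (p_null < alpha).mean() <= 0.07
        effect = rng.standard_normal((reps, n)) + 0.8
        t_eff = effect.mean(1) / (effect.std(1, ddof=1) / np.sqrt(n))
        p_eff = 2 * scipy.stats.t.sf(np.abs(t_eff), n - 1)
        assert (p_eff < alpha).mean() >= 0.85


class TestChiSquare:
    def test_valence_frequency_example(self):
        res = chi_square_gof([3, 30], [16.5, 16.5])
        assert res.statistic == pytest.approx(22.09, abs=0.005)
        assert res.df == (1,)

    def test_observed_equal_expected(self):
        assert chi_square_gof([10, 10], [10, 10]).statistic == 0.0

    def test_hand_computed(self):
        res = chi_square_gof([10, 20], [15, 15])
        assert res.statistic == pytest.approx(10 / 3)

    def test_nonpositive_expectation_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof([1, 2], [0, 3])


class TestWithinInteraction:
    def test_additive_data_has_no_interaction(self, rng):
        # integer-valued cells so the double differences cancel exactly
        n = 12
        row = rng.integers(-5, 5, (n, 2, 1)).astype(float)
        col = rng.integers(-5, 5, (n, 1, 2)).astype(float)
        cells = row + col
        res = within_interaction_univariate(cells)
        assert res.statistic == 0.0

    def test_f_is_squared_paired_t_on_double_difference(self, rng):
        cells = rng.standard_normal((10, 2, 2))
        g = (cells[:, 0, 0] - cells[:, 0, 1]) - (cells[:, 1, 0] - cells[:, 1, 1])
        t = paired_t(g, np.zeros_like(g))
        res = within_interaction_univariate(cells)
        assert res.statistic == pytest.approx(t.statistic ** 2)

    def test_univariate_matches_reference_rm_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        cells = rng.standard_normal((8, 2, 2))
        res = within_interaction_univariate(cells)
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(8), 4),
            "A": np.tile([0, 0, 1, 1], 8),
            "B": np.tile([0, 1, 0, 1], 8),
            "y": cells.reshape(-1),
        })
        aov = pg.rm_anova(dv="y", within=["A", "B"], subject="subj",
                          data=long, detailed=True)
        f_ref = float(aov.loc[aov["Source"] == "A * B", "F"].iloc[0])
        assert res.statistic == pytest.approx(f_ref, abs=1e-6)

    def test_zero_double_differences_give_identity_lambda(self, rng):
        base = rng.standard_normal((9, 1, 1, 2))
        cells = np.tile(base, (1, 2, 2, 1))
        res = within_interaction_multivariate(cells)
        assert res.extra["hotelling_T2"] == pytest.approx(0.0, abs=1e-18)
        assert res.extra["wilks_lambda"] == pytest.approx(1.0)

    def test_duplicated_dv_approaches_univariate_f(self, rng):
        cells = rng.standard_normal((15, 2, 2))
        cells[:, 0, 0] += 5.0          # strong interaction so T² dominates
        jitter = 1e-5 * rng.standard_normal(cells.shape)
        stacked = np.stack([cells, cells + jitter], axis=3)
        uni = within_interaction_univariate(cells)
        mv = within_interaction_multivariate(stacked)
        # for one DV, T² equals the squared paired t, i.e. the univariate F
        assert mv.extra["hotelling_T2"] == pytest.approx(uni.statistic, rel=0.1)

    def test_multivariate_matches_reference_hotelling(self, rng):
        pg = pytest.importorskip("pingouin")
        cells = rng.standard_normal((10, 2, 2, 2))
        res = within_interaction_multivariate(cells)
        G = (cells[:, 0, 0] - cells[:, 0, 1]) - (cells[:, 1, 0] - cells[:, 1, 1])
        ref = pg.multivariate_ttest(G)
        assert res.extra["hotelling_T2"] == pytest.approx(
            float(ref["T2"].iloc[0]), abs=1e-6)
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), abs=1e-6)

    def test_singular_covariance_rejected(self):
        cells = np.zeros((5, 2, 2, 2))
        cells[:, 0, 0, :] = np.arange(5)[:, None]  # both DVs identical
        with pytest.raises(ValueError, match="singular"):
            within_interaction_multivariate(cells)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        res = partial_correlation(x, y)
        assert res.statistic == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_shared_driver_partialled_out(self, rng):
        n = 4000
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n)
        y = z + rng.standard_normal(n)
        res = partial_correlation(x, y, z)
        assert abs(res.statistic) < 0.05
        assert partial_correlation(x, y).statistic > 0.4

    def test_closed_form_three_variable_identity(self, rng):
        n = 600
        data = rng.standard_normal((n, 3)) @ np.linalg.cholesky(
            np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])).T
        x, y, z = data.T
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expected = (r_xy - r_xz * r_yz) / np.sqrt(
            (1 - r_xz ** 2) * (1 - r_yz ** 2))
        res = partial_correlation(x, y, z)
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_matches_reference_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.standard_normal((40, 4)),
                          columns=["x", "y", "c1", "c2"])
        res = partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        ref = pg.partial_corr(data=df, x="x", y="y", covar=["c1", "c2"])
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3], [1, 2, 3], [[1], [2], [3]])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_step_up_invariants(self, pvals):
        """Adjusted p's never fall below raw, never exceed 1, and preserve
        the ordering of the raw p-values."""
        p = np.asarray(pvals)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_saturated_adjustment_is_a_fixed_point(self):
        """A fully tied step-up result re-adjusts to itself."""
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_fdr(adj), adj)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestStepwise:
    def test_constant_response_gives_intercept_only(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 4)),
                         columns=list("abcd"))
        model = stepwise_regression(X, np.full(50, 3.0))
        assert model.predictors == []
        assert model.adj_r2 == 0.0

    def test_single_informative_predictor_recovered(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((200, 5)),
                         columns=[f"x{i}" for i in range(5)])
        y = 2.0 * X["x0"] + 0.1 * rng.standard_normal(200)
        model = stepwise_regression(X, y)
        assert model.predictors == ["x0"]
        assert model.adj_r2 > 0.99
        assert model.coef["x0"] == pytest.approx(2.0, abs=0.05)

    def test_result_is_a_fixed_point_of_the_entry_removal_rules(self, rng):
        """Brute-force check: no excluded candidate could enter, and every
        included predictor survives the removal rule."""
        import statsmodels.api as sm
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        y = X["a"] * 0.8 + 0.5 * rng.standard_normal(40)
        model = stepwise_regression(X, y, p_enter=0.05, p_remove=0.10)

        def pvalues(cols):
            fit = sm.OLS(y, sm.add_constant(X[list(cols)])).fit()
            return fit.pvalues.drop("const")

        inside = model.predictors
        if inside:
            assert (pvalues(inside) <= 0.10 + 1e-12).all()
        for col in set("abc") - set(inside):
            p = pvalues(inside + [col])[col]
            assert p >= 0.05

    def test_standardized_coefficients_consistent(self, rng):
        X = pd.DataFrame(rng.standard_normal((120, 2)), columns=["u", "v"])
        y = X["u"] + 0.2 * rng.standard_normal(120)
        model = stepwise_regression(X, y)
        beta_hand = model.coef["u"] * X["u"].std(ddof=1) / np.std(y, ddof=1)
        assert model.beta["u"] == pytest.approx(beta_hand)

    def test_crossed_thresholds_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="cycling"):
            stepwise_regression(X, rng.standard_normal(20), p_enter=0.2,
                                p_remove=0.1)
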