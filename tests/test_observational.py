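"""Weighted association model, diagnostics, and descriptives, with an
independent normal-equations / statsmodels oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mealmr._regression import RankDeficientError, wls
from mealmr.observational import (
    anova_eta_squared,
    association_scan,
    breusch_pagan,
    covariable_screen,
    describe_states,
    fit_weighted_glm,
)
from mealmr.simulate import SynthConfig, generate_cohort


def _cohort_frame(data):
    return data.cohort.set_index("individual_id", drop=False)


@pytest.fixture(scope="module")
def orthogonal_data():
    """Covariates carrying no BMI variance, for perfect-fit examples."""
    cfg = SynthConfig(
        n_random=600,
        n_oversampled=600,
        oversample_threshold=0.0,
        date_structure_r2=0.0,
        agesex_r2=0.0,
        n_snps=10,
        n_metabolites=2,
        seed=13,
    )
    return generate_cohort(cfg)


class TestWlsOracle:
    def test_matches_statsmodels(self, rng):
        for _ in range(10):
            n = 80
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            y = X @ rng.normal(size=4) + rng.normal(size=n)
            w = rng.uniform(0.5, 2.0, n)
            mine = wls(y, X, weights=w)
            ref = sm.WLS(y, X, weights=w).fit()
            np.testing.assert_allclose(mine.params, ref.params, atol=1e-8)
            np.testing.assert_allclose(mine.bse, ref.bse, atol=1e-8)
            np.testing.assert_allclose(mine.pvalues, ref.pvalues, atol=1e-8)

    def test_equal_weights_reproduce_ols(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        a = wls(y, X)
        b = wls(y, X, weights=np.full(n, 3.0))
        np.testing.assert_allclose(a.params, b.params, atol=1e-12)
        np.testing.assert_allclose(a.bse, b.bse, atol=1e-12)

    def test_rank_deficient_names_columns(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(RankDeficientError) as err:
            wls(rng.normal(size=n), X, names=["intercept", "x", "x_copy"])
        assert "x_copy" in err.value.columns


class TestFitWeightedGlm:
    def test_null_outcome_p_uniform(self, small_data, rng):
        cohort = _cohort_frame(small_data)
        pvals = []
        for _ in range(400):
            y = pd.Series(rng.normal(size=len(cohort)), index=cohort.index)
            rec, _ = fit_weighted_glm(y, cohort, use_weights=False)
            pvals.append(rec["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_fit_limit(self, orthogonal_data):
        cohort = _cohort_frame(orthogonal_data)
        y = cohort["bmi"].copy()
        rec, _ = fit_weighted_glm(y, cohort, use_weights=False)
        assert rec["beta"] == pytest.approx(1.0, abs=1e-10)
        assert rec["p"] < 1e-100
        assert rec["eta2_bmi"] > 0.95
        assert rec["eta2_model"] == pytest.approx(1.0, abs=1e-10)

    def test_recovers_generating_beta(self, small_data):
        from mealmr.transforms import rint_matrix

        cohort = _cohort_frame(small_data)
        fast = rint_matrix(small_data.fasting, seed=1)
        trait = small_data.truth.loc[0, "trait"]
        assert small_data.truth.loc[0, "beta_fasting"] == pytest.approx(0.07)
        rec, _ = fit_weighted_glm(fast[trait], cohort)
        assert abs(rec["beta"] - 0.07) < 3 * rec["se"]

    def test_weighted_equals_unweighted_when_flat(self, small_data):
        cohort = _cohort_frame(small_data).copy()
        cohort["sample_weight"] = 1.0
        y = small_data.fasting.iloc[:, 0]
        r1, _ = fit_weighted_glm(y, cohort, use_weights=True)
        r2, _ = fit_weighted_glm(y, cohort, use_weights=False)
        assert r1["beta"] == pytest.approx(r2["beta"], abs=1e-12)
        assert r1["se"] == pytest.approx(r2["se"], abs=1e-12)

    def test_confounder_adjustment(self):
        cfg = SynthConfig(
            n_random=1000,
            n_oversampled=1500,
            n_snps=20,
            n_metabolites=4,
            beta_fasting=0.05,
            date_confounding_beta=0.8,
            seed=31,
        )
        data = generate_cohort(cfg)
        cohort = data.cohort.set_index("individual_id", drop=False)
        cohort["_date_z"] = data.cohort.set_index("individual_id")["_date_z"]
        y = data.fasting.iloc[:, 0]
        with_date, _ = fit_weighted_glm(y, cohort, use_weights=False)
        without, _ = fit_weighted_glm(
            y, cohort, use_weights=False, covariates=["subpopulation", "age", "sex"]
        )
        assert abs(with_date["beta"] - 0.05) < 3 * with_date["se"]
        assert abs(without["beta"] - with_date["beta"]) > 3 * with_date["se"]


class TestBreuschPagan:
    def test_matches_statsmodels(self, rng):
        for _ in range(5):
            n = 120
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = X @ np.array([1.0, 0.5, -0.3]) + rng.normal(size=n) * (1 + 0.5 * np.abs(X[:, 1]))
            fit = wls(y, X)
            lm, p = breusch_pagan(fit, X)
            ref_lm, ref_p, _, _ = sm.stats.diagnostic.het_breuschpagan(fit.resid, X)
            assert lm == pytest.approx(ref_lm, rel=1e-8)
            assert p == pytest.approx(ref_p, rel=1e-8)

    def test_size_calibration(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            n = 100
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = X @ np.array([0.5, 1.0]) + rng.normal(size=n)
            fit = wls(y, X)
            _, p = breusch_pagan(fit, X)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_bmi_squared_variance(self, small_data, rng):
        cohort = _cohort_frame(small_data)
        bmi = cohort["bmi"].to_numpy()
        ps = []
        for _ in range(20):
            y = pd.Series(
                0.02 * bmi + rng.normal(size=len(bmi)) * (bmi / bmi.mean()) ** 2,
                index=cohort.index,
            )
            rec, _ = fit_weighted_glm(y, cohort, use_weights=False)
            ps.append(rec["bp_p"])
        assert np.median(ps) < 0.001

    def test_zero_r2_gives_lm_zero(self):
        n = 40
        X = np.ones((n, 1))
        y = np.arange(n, dtype=float)
        fit = wls(y, X)
        lm, p = breusch_pagan(fit, X)
        assert lm == 0.0 and p == 1.0


class TestEtaSquared:
    def test_orthonormal_equal_split(self):
        n = 100
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x1 = np.cos(t) / np.linalg.norm(np.cos(t))
        x2 = np.sin(t) / np.linalg.norm(np.sin(t))
        y = x1 + x2
        X = np.column_stack([np.ones(n), x1, x2])
        eta_model, eta_last = anova_eta_squared(y, X, ["intercept", "x1", "x2"], np.ones(n), "x2")
        assert eta_model == pytest.approx(1.0, abs=1e-10)
        assert eta_last == pytest.approx(0.5, abs=1e-10)

    def test_null_outcome_near_zero(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 4))])
        y = rng.normal(size=n)
        names = ["intercept", "a", "b", "c", "bmi"]
        eta_model, eta_bmi = anova_eta_squared(y, X, names, np.ones(n), "bmi")
        assert eta_model < 0.01 and eta_bmi < 0.01

    def test_zero_total_ss_error(self):
        n = 20
        X = np.ones((n, 2))
        with pytest.raises(ValueError):
            anova_eta_squared(np.full(n, 1.0), X, ["intercept", "x"], np.ones(n), "x")


class TestDescribeStates:
    def test_constant_shift(self, small_data):
        fast = small_data.fasting
        post = fast + 1.0
        res = describe_states(fast, post).set_index("trait")
        assert (res["mean_delta"] - 1.0).abs().max() < 1e-12
        assert res["zero_variance"].all()

    def test_identical_matrices(self, small_data):
        res = describe_states(small_data.fasting, small_data.fasting)
        assert (res["t"] == 0.0).all()
        assert (res["p"] == 1.0).all()

    def test_expected_t_statistic(self, rng):
        n = 400
        fast = pd.DataFrame({"a": rng.normal(size=n)})
        post = fast + pd.DataFrame({"a": rng.normal(0.5, 1.0, size=n)})
        res = describe_states(fast, post)
        assert abs(res.loc[0, "t"] - 10.0) < 3.0


class TestCovariableScreen:
    def test_bmi_proxy_flagged(self, small_data, rng):
        cohort = _cohort_frame(small_data).copy()
        cohort["pgs"] = rng.normal(size=len(cohort))  # independent of everything
        cohort["bmi_proxy"] = cohort["bmi"] + rng.normal(scale=0.5, size=len(cohort))
        res = covariable_screen(
            cohort, small_data.fasting, ["bmi_proxy"], m_eff=54, use_weights=False
        ).set_index("covariable")
        assert res.loc["bmi_proxy", "flag_bmi"]
        assert not res.loc["bmi_proxy", "flag_pgs"]

    def test_threshold_value(self, small_data, rng):
        cohort = _cohort_frame(small_data).copy()
        cohort["pgs"] = rng.normal(size=len(cohort))
        cohort["noise"] = rng.normal(size=len(cohort))
        res = covariable_screen(cohort, small_data.fasting, ["noise"], m_eff=54)
        assert res.attrs["threshold"] == pytest.approx(9.26e-4, rel=1e-3)

    def test_nonvarying_skipped(self, small_data, rng):
        cohort = _cohort_frame(small_data).copy()
        cohort["pgs"] = rng.normal(size=len(cohort))
        cohort["flat"] = 1.0
        res = covariable_screen(cohort, small_data.fasting, ["flat"], m_eff=10)
        assert res.empty


class TestAssociationScan:
    def test_row_per_trait(self, small_data):
        table = association_scan(small_data.fasting, small_data.cohort, "fasting")
        assert len(table) == small_data.fasting.shape[1]
        assert (table["state"] == "fasting").all()
        assert (table["se"] > 0).all()
        assert table["p"].between(0, 1).all()
        assert (table["eta2_bmi"] <= table["eta2_model"] + 1e-12).all()
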