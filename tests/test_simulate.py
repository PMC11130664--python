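"""Synthetic-cohort generator: calibration, determinism, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from mealmr import qc
from mealmr.simulate import (
    SynthConfig,
    derive_sample_weights,
    generate_bmi,
    generate_cohort,
    generate_genotypes,
    generate_metabolites,
    generate_weight_table,
    inject_missing_and_outliers,
    make_skeleton,
    true_pgs,
)


def _mini(**kw):
    base = dict(n_random=500, n_oversampled=500, n_snps=20, n_metabolites=6, n_classes=3, seed=5)
    base.update(kw)
    return SynthConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_snps": 0},
            {"n_metabolites": 0},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"missing_rate": 1.0},
            {"pgs_variance_explained": 0.99},  # fractions sum >= 1 with date r2
        ],
    )
    def test_rejected(self, kw):
        with pytest.raises(ValueError):
            _mini(**kw)


class TestGenotypes:
    def test_mean_dosage_at_half(self):
        cfg = _mini(n_random=5000, n_oversampled=5000, n_snps=1, maf_range=(0.5, 0.5))
        g = generate_genotypes(cfg)
        assert 0.95 < g.dosages.mean() < 1.05

    def test_dosage_bounds_and_frequency(self):
        cfg = _mini(n_random=600, n_oversampled=600)
        g = generate_genotypes(cfg)
        assert g.dosages.min() >= 0 and g.dosages.max() <= 2
        emp = g.dosages.mean(axis=0) / 2.0
        np.testing.assert_allclose(emp, g.variants["frequency"], atol=0.05)

    def test_deterministic(self):
        cfg = _mini()
        g1, g2 = generate_genotypes(cfg), generate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(g1.variants, g2.variants)


class TestBMI:
    def test_r2_calibrated(self):
        cfg = _mini(n_random=1500, n_oversampled=3500, n_snps=60, seed=21)
        g = generate_genotypes(cfg)
        w = generate_weight_table(cfg, g)
        cohort = generate_bmi(make_skeleton(cfg), g, w, cfg)
        pgs = true_pgs(g, w)[cohort["genotype_row"].to_numpy()]
        r2 = np.corrcoef(pgs, cohort["bmi"])[0, 1] ** 2
        assert 0.03 < r2 < 0.06

    def test_null_pgs(self):
        cfg = _mini(n_random=2500, n_oversampled=2500, pgs_variance_explained=0.0, seed=1)
        g = generate_genotypes(cfg)
        w = generate_weight_table(cfg, g)
        cohort = generate_bmi(make_skeleton(cfg), g, w, cfg)
        pgs = true_pgs(g, w)[cohort["genotype_row"].to_numpy()]
        assert abs(np.corrcoef(pgs, cohort["bmi"])[0, 1]) < 0.03

    def test_oversampled_above_threshold(self, small_data):
        c = small_data.cohort
        assert c.loc[c["subpopulation"] == "oversampled", "bmi"].min() > 27.0

    def test_dates_monotone_within_batch(self, small_data):
        for _, g in small_data.cohort.groupby("subpopulation"):
            assert g["visit_date"].is_monotonic_increasing

    def test_date_explains_bmi(self, small_data):
        c = small_data.cohort
        r2 = np.corrcoef(c["_date_z"], c["bmi"])[0, 1] ** 2
        assert r2 > 0.05  # date trend present (selection attenuates the 0.20 input)


class TestMetabolites:
    def test_fasting_postprandial_correlated(self, small_data):
        for trait in small_data.fasting.columns:
            r = small_data.fasting[trait].corr(small_data.postprandial[trait])
            assert r > 0.3

    def test_class_structure(self, small_data):
        fast = small_data.fasting
        classes = small_data.truth.set_index("trait")["metabolite_class"]
        corr = fast.corr().abs().to_numpy()
        same = np.equal.outer(classes.to_numpy(), classes.to_numpy())
        np.fill_diagonal(same, False)
        off = ~same
        np.fill_diagonal(off, False)
        assert corr[same].mean() > corr[off].mean() + 0.1

    def test_degenerate_limit_post_equals_fast(self):
        cfg = _mini(passthrough_slope=1.0, min_noise_var=0.0)
        data = generate_cohort(cfg)
        # var_e2 = 1 - s^2 = 0 with no direct BMI term: exact pass-through
        np.testing.assert_allclose(
            data.postprandial.to_numpy(), data.fasting.to_numpy(), atol=1e-10
        )

    def test_unit_scale(self, small_data):
        sds = small_data.fasting.std()
        assert ((sds > 0.8) & (sds < 1.2)).all()

    def test_requires_bmi(self, small_data):
        cohort = small_data.cohort.copy()
        cohort.loc[cohort.index[0], "bmi"] = np.nan
        with pytest.raises(ValueError):
            generate_metabolites(cohort, small_data.config)


class TestSampleWeights:
    @staticmethod
    def _identical_strata_cfg(n, seed=3, **kw):
        return SynthConfig(
            n_random=n,
            n_oversampled=n,
            oversample_threshold=0.0,
            date_structure_r2=0.0,
            n_snps=5,
            n_metabolites=2,
            seed=seed,
            **kw,
        )

    def test_identical_distributions_unit_weights(self):
        data = generate_cohort(self._identical_strata_cfg(2000))
        cohort = derive_sample_weights(data.cohort, n_bins=4)
        w = cohort.loc[cohort["subpopulation"] == "oversampled", "sample_weight"]
        assert (w - 1.0).abs().max() < 0.1

    def test_two_bin_toy_raw_ratio(self):
        rng = np.random.default_rng(0)
        bmi_rand = np.r_[rng.uniform(10, 19.9, 50), rng.uniform(20.1, 30, 50)]
        bmi_over = np.r_[rng.uniform(10, 19.9, 25), rng.uniform(20.1, 30, 75)]
        cohort = pd.DataFrame(
            {
                "subpopulation": ["random"] * 100 + ["oversampled"] * 100,
                "bmi": np.r_[bmi_rand, bmi_over],
                "sample_weight": 1.0,
            }
        )
        out = derive_sample_weights(cohort, n_bins=2)
        raw = out.attrs["weight_bins"]["raw_weight"].to_numpy()
        np.testing.assert_allclose(raw, [2.0, 2.0 / 3.0], rtol=1e-12)

    def test_weighted_mean_matches_random_stratum(self):
        data = generate_cohort(self._identical_strata_cfg(3000))
        cohort = derive_sample_weights(data.cohort)
        over = cohort[cohort["subpopulation"] == "oversampled"]
        rand_mean = cohort.loc[cohort["subpopulation"] == "random", "bmi"].mean()
        wmean = np.average(over["bmi"], weights=over["sample_weight"])
        assert abs(wmean - rand_mean) < 0.5

    def test_weighted_histogram_matches(self):
        from scipy import stats

        data = generate_cohort(self._identical_strata_cfg(3000))
        cohort = derive_sample_weights(data.cohort)
        rand = cohort[cohort["subpopulation"] == "random"]
        over = cohort[cohort["subpopulation"] == "oversampled"]
        edges = np.quantile(rand["bmi"], np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        obs, _ = np.histogram(over["bmi"], bins=edges, weights=over["sample_weight"])
        exp, _ = np.histogram(rand["bmi"], bins=edges)
        exp = exp / exp.sum() * obs.sum()
        keep = exp > 0
        chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.05

    def test_mean_one_within_stratum(self, small_data):
        over = small_data.cohort[small_data.cohort["subpopulation"] == "oversampled"]
        assert over["sample_weight"].mean() == pytest.approx(1.0)
        rand = small_data.cohort[small_data.cohort["subpopulation"] == "random"]
        assert (rand["sample_weight"] == 1.0).all()

    def test_empty_stratum_rejected(self):
        cohort = pd.DataFrame(
            {"subpopulation": ["random"] * 10, "bmi": np.arange(10.0), "sample_weight": 1.0}
        )
        with pytest.raises(ValueError):
            derive_sample_weights(cohort)


class TestInjection:
    def test_identity_at_zero_rates(self, small_data):
        out, inj = inject_missing_and_outliers(small_data.fasting, small_data.config)
        pd.testing.assert_frame_equal(out, small_data.fasting)
        assert inj.empty

    def test_missing_fraction(self):
        from dataclasses import replace

        cfg = _mini(n_random=1000, n_oversampled=1000, n_metabolites=20, missing_rate=0.05)
        data = generate_cohort(replace(cfg, missing_rate=0.0))
        out, inj = inject_missing_and_outliers(data.fasting, cfg)
        frac = out.isna().to_numpy().mean()
        assert 0.04 <= frac <= 0.06

    def test_outliers_flagged_by_iqr_filter(self):
        from dataclasses import replace

        cfg = _mini(n_random=800, n_oversampled=800, n_metabolites=10, outlier_rate=0.01)
        clean = generate_cohort(replace(cfg, outlier_rate=0.0))
        out, inj = inject_missing_and_outliers(clean.fasting, cfg)
        filtered = qc.iqr_filter(out, k=10.0)
        planted = inj[inj["kind"] == "outlier"]
        assert len(planted) > 0
        for rec in planted.itertuples(index=False):
            assert np.isnan(filtered.loc[rec.individual_id, rec.trait])


class TestDeterminismAndRecovery:
    def test_full_determinism(self, small_cfg, small_data):
        again = generate_cohort(small_cfg)
        pd.testing.assert_frame_equal(again.cohort, small_data.cohort)
        pd.testing.assert_frame_equal(again.fasting, small_data.fasting)
        np.testing.assert_array_equal(again.genotypes.dosages, small_data.genotypes.dosages)

    def test_response_beta_recovery(self, small_data):
        """Deming residual of a response-effect trait regressed on BMI
        recovers the generating slope within 3 SE."""
        from mealmr._regression import wls
        from mealmr.response import deming_fit, deming_residuals

        truth = small_data.truth.set_index("trait")
        cohort = small_data.cohort
        trait = truth.index[10]  # beta_response = -0.08 group
        assert truth.loc[trait, "beta_response"] == pytest.approx(-0.08)
        x = small_data.fasting[trait].to_numpy()
        y = small_data.postprandial[trait].to_numpy()
        fit = deming_fit(x, y)
        resid = deming_residuals(fit, x, y)
        X = np.column_stack([np.ones(len(resid)), cohort["bmi"].to_numpy()])
        lm = wls(resid, X, names=["intercept", "bmi"])
        beta, se, _ = lm.coef("bmi")
        assert abs(beta - (-0.08)) < 3 * se
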