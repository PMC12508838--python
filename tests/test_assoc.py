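"""OLS engine, GWAS and GWIS scans: oracles, calibration, invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ppgs_gxe.assoc import (
    DesignError,
    build_covariate_matrix,
    gaussian_loglik,
    gwas_main,
    gwis_interaction,
    ols_fit,
)
from ppgs_gxe.config import CovariateSpec
from ppgs_gxe.containers import GenotypeMatrix


class TestOlsFit:
    def test_exact_fit_no_noise(self):
        x = np.linspace(-1, 1, 50)
        X = np.column_stack([np.ones(50), x])
        fit = ols_fit(X, 2.0 * x, terms=["const", "x"])
        assert fit.term("x")[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10000)
        y = 0.3 * x + rng.standard_normal(10000)
        fit = ols_fit(np.column_stack([np.ones(10000), x]), y, terms=["const", "x"])
        beta, se, _ = fit.term("x")
        assert abs(beta - 0.3) < 2 * se

    def test_robust_matches_model_based_under_homoskedasticity(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(10000), rng.standard_normal((10000, 3))])
        y = X @ np.array([0.1, 0.5, -0.2, 0.0]) + rng.standard_normal(10000)
        plain = ols_fit(X, y)
        robust = ols_fit(X, y, robust="hc3")
        np.testing.assert_allclose(robust.se, plain.se, rtol=0.05)

    @pytest.mark.parametrize("flavor", [None, "hc0", "hc1", "hc3"])
    def test_matches_statsmodels(self, flavor):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 4))])
        y = X @ rng.standard_normal(5) + rng.standard_normal(300) * (1 + 0.5 * np.abs(X[:, 1]))
        fit = ols_fit(X, y, robust=flavor)
        ref = sm.OLS(y, X).fit() if flavor is None else sm.OLS(y, X).fit(cov_type=flavor.upper())
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-8)
        assert fit.loglik == pytest.approx(sm.OLS(y, X).fit().llf, abs=1e-6)

    def test_rank_deficient_names_collinear_column(self):
        x = np.random.default_rng(3).standard_normal(50)
        X = pd.DataFrame({"const": np.ones(50), "a": x, "b": 2 * x})
        with pytest.raises(DesignError, match="collinear"):
            ols_fit(X, x)

    def test_n_not_greater_than_p_rejected(self):
        with pytest.raises(DesignError, match="must exceed"):
            ols_fit(np.eye(3), np.ones(3))

    def test_loglik_monotone_in_nested_terms(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 5))])
        y = rng.standard_normal(200)
        lls = [ols_fit(X[:, : k + 1], y).loglik for k in range(1, 6)]
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))


class TestCovariateMatrix:
    def test_expansion_columns(self, null_dataset, covariates):
        Z = build_covariate_matrix(null_dataset["pheno"], covariates, exposure_col="exposure")
        expected = (
            ["age", "age_sq", "sex", "age_by_sex"]
            + [f"gpc_{k}" for k in range(1, 11)]
            + ["exposure"]
            + [f"exposure_by_gpc_{k}" for k in range(1, 11)]
        )
        assert list(Z.columns) == expected

    def test_missing_column_named(self, covariates):
        pheno = pd.DataFrame({"age": [1.0, 2.0], "sex": [0, 1]})
        with pytest.raises(DesignError, match="gpc_1"):
            build_covariate_matrix(pheno, covariates)


class TestGwasMain:
    def test_matches_per_variant_full_refit(self, null_dataset, covariates):
        d = null_dataset
        ss = gwas_main(d["genotypes"], d["pheno"], covariates)
        Z = build_covariate_matrix(d["pheno"], covariates)
        Zm = np.column_stack([np.ones(len(d["pheno"])), Z.to_numpy()])
        y = d["pheno"]["outcome"].to_numpy()
        G = d["genotypes"].imputed()
        rng = np.random.default_rng(0)
        by_id = ss.set_index("variant_id")
        for j in rng.choice(d["genotypes"].n_variants, 12, replace=False):
            X = np.column_stack([Zm, G[:, j]])
            fit = ols_fit(X, y)
            vid = d["genotypes"].variant_ids[j]
            assert by_id.at[vid, "beta"] == pytest.approx(fit.params[-1], abs=1e-8)
            assert by_id.at[vid, "se"] == pytest.approx(fit.se[-1], abs=1e-8)
            assert by_id.at[vid, "p"] == pytest.approx(fit.p[-1], rel=1e-6)

    def test_parameter_recovery_strong_variant(self, signal_dataset, covariates):
        d = signal_dataset
        ss = gwas_main(d["genotypes"], d["pheno"], covariates).set_index("variant_id")
        truth = d["truth"]
        strong = sorted(truth["beta"], key=lambda v: -abs(truth["beta"][v]))[:5]
        hits = sum(abs(ss.at[v, "beta"]) > 2 * ss.at[v, "se"] for v in strong)
        assert hits >= 4  # strong simulated effects are detected

    def test_null_calibration_permuted_outcome(self, null_dataset, covariates):
        d = null_dataset
        pheno = d["pheno"].copy()
        rng = np.random.default_rng(11)
        pheno["outcome"] = rng.permutation(pheno["outcome"].to_numpy())
        ss = gwas_main(d["genotypes"], pheno, covariates)
        frac = (ss["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_duplicated_variant_identical_rows(self, null_dataset, covariates):
        d = null_dataset
        geno = d["genotypes"]
        var2 = pd.concat([geno.variants.iloc[:1]] * 2, ignore_index=True)
        var2.loc[1, "variant_id"] = "rs_dup"
        dup = GenotypeMatrix(np.column_stack([geno.dosages[:, 0]] * 2), var2, geno.samples)
        ss = gwas_main(dup, d["pheno"], covariates)
        assert ss["beta"].iloc[0] == ss["beta"].iloc[1]
        assert ss["p"].iloc[0] == ss["p"].iloc[1]

    def test_monomorphic_flagged_with_p_one(self, null_dataset, covariates):
        d = null_dataset
        geno = d["genotypes"]
        var = geno.variants.iloc[:2].copy()
        var.loc[1, "variant_id"] = "rs_mono"
        dosages = np.column_stack([geno.dosages[:, 0], np.full(geno.n_samples, 2.0)])
        ss = gwas_main(GenotypeMatrix(dosages, var, geno.samples), d["pheno"], covariates)
        row = ss.set_index("variant_id").loc["rs_mono"]
        assert row["p"] == 1.0 and row["flag"] == "monomorphic"


class TestGwisInteraction:
    def small(self, dataset, n_variants=8):
        geno = dataset["genotypes"]
        return GenotypeMatrix(
            geno.dosages[:, :n_variants], geno.variants.iloc[:n_variants], geno.samples
        )

    def test_matches_statsmodels_hc3(self, null_dataset, covariates):
        d = null_dataset
        geno = self.small(d)
        ss = gwis_interaction(geno, d["pheno"], covariates)
        Z = build_covariate_matrix(d["pheno"], covariates, exposure_col="exposure")
        y = d["pheno"]["outcome"].to_numpy()
        e = d["pheno"]["exposure"].to_numpy()
        for j in range(geno.n_variants):
            g = geno.imputed()[:, j]
            X = np.column_stack([np.ones(len(y)), Z.to_numpy(), g, g * e])
            ref = sm.OLS(y, X).fit(cov_type="HC3")
            assert ss["beta"].iloc[j] == pytest.approx(ref.params[-1], abs=1e-8)
            assert ss["se"].iloc[j] == pytest.approx(ref.bse[-1], abs=1e-8)

    def test_interaction_recovery(self, covariates):
        """A variant given a standardized interaction effect is recovered
        within 2 robust SE."""
        rng = np.random.default_rng(21)
        n = 10000
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.standard_normal(n)
        gz = (g - g.mean()) / g.std()
        y_raw = 0.05 * g + 0.08 * gz * e + rng.standard_normal(n)
        y = (y_raw - y_raw.mean()) / y_raw.std()
        target = 0.08 / y_raw.std()  # standardized injected interaction
        pheno = pd.DataFrame({"outcome": y, "exposure": e, "age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n).astype(float)})
        for k in range(1, 11):
            pheno[f"gpc_{k}"] = rng.standard_normal(n)
        var = pd.DataFrame({"variant_id": ["v1"], "chrom": ["1"], "pos": [100], "ref": ["A"], "alt": ["G"], "maf": [0.3]})
        geno = GenotypeMatrix(g[:, None], var, [f"s{i}" for i in range(n)])
        ss = gwis_interaction(geno, pheno, covariates)
        beta_per_allele = ss["beta"].iloc[0]
        beta_std = beta_per_allele * g.std()
        se_std = ss["se"].iloc[0] * g.std()
        assert abs(beta_std - target) < 2 * se_std

    def test_constant_exposure_rejected(self, null_dataset, covariates):
        d = null_dataset
        pheno = d["pheno"].copy()
        pheno["exposure"] = 0.0
        with pytest.raises(DesignError, match="constant"):
            gwis_interaction(self.small(d), pheno, covariates)

    def test_monomorphic_variant_flagged_not_dropped(self, null_dataset, covariates):
        d = null_dataset
        geno = self.small(d, 2)
        dosages = geno.dosages.copy()
        dosages[:, 1] = 2.0
        geno = GenotypeMatrix(dosages, geno.variants, geno.samples)
        ss = gwis_interaction(geno, d["pheno"], covariates)
        assert len(ss) == 2
        flagged = ss[ss["flag"] == "degenerate_interaction"]
        assert len(flagged) == 1 and flagged["p"].iloc[0] == 1.0

    def test_row_order_and_covariate_scaling_invariance(self, null_dataset, covariates):
        d = null_dataset
        geno = self.small(d, 4)
        base = gwis_interaction(geno, d["pheno"], covariates)

        perm = np.random.default_rng(5).permutation(geno.n_samples)
        shuffled = gwis_interaction(
            geno.subset_samples(perm), d["pheno"].iloc[perm].reset_index(drop=True), covariates
        )
        np.testing.assert_allclose(shuffled["p"], base["p"], atol=1e-10)

        rescaled_pheno = d["pheno"].copy()
        rescaled_pheno["age"] = rescaled_pheno["age"] * 3.0 + 7.0
        rescaled = gwis_interaction(geno, rescaled_pheno, covariates)
        np.testing.assert_allclose(rescaled["p"], base["p"], atol=1e-10)


def test_gaussian_loglik_matches_statsmodels():
    rng = np.random.default_rng(6)
    X = np.column_stack([np.ones(100), rng.standard_normal(100)])
    y = rng.standard_normal(100)
    ref = sm.OLS(y, X).fit()
    rss = float(ref.resid @ ref.resid)
    assert gaussian_loglik(rss, 100) == pytest.approx(ref.llf, abs=1e-8)
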