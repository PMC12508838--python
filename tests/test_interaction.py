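"""PGS×E tests, Bonferroni scan, joint LRT, sensitivity and split-sample checks."""

import numpy as np
import pandas as pd
import pytest

from ppgs_gxe.assoc import DesignError, gwas_main
from ppgs_gxe.config import ClumpConfig, CovariateSpec
from ppgs_gxe.containers import ScoreVector
from ppgs_gxe.interaction import (
    joint_lrt,
    pgs_by_e_test,
    run_ppgs_scan,
    sensitivity_exposure_pgs,
    split_sample_eval,
)
from ppgs_gxe.pgs import build_gwpgs, build_ppgs, compute_score

from conftest import make_dataset
from ppgs_gxe.config import SimulationConfig


def score_from(values, scope="s"):
    v = np.asarray(values, dtype=float)
    return ScoreVector(scope=scope, raw=v, standardized=(v - v.mean()) / v.std(), n_variants=1)


@pytest.fixture(scope="module")
def fitted(signal_dataset, covariates, clump_config):
    d = signal_dataset
    ss = gwas_main(d["genotypes"], d["pheno"], covariates)
    gw = build_gwpgs(ss, d["genotypes"], clump_config)
    ppgs_w, excluded = build_ppgs(gw, d["pv_sets"], ss)
    return {
        "sumstats": ss,
        "gw_score": compute_score(d["genotypes"], gw),
        "ppgs_scores": [compute_score(d["genotypes"], w) for w in ppgs_w],
        "excluded": excluded,
    }


class TestPgsByETest:
    def test_sign_symmetry_under_outcome_negation(self, signal_dataset, covariates, fitted):
        d = signal_dataset
        r1 = pgs_by_e_test(fitted["gw_score"], d["pheno"], covariates)
        flipped = d["pheno"].copy()
        flipped["outcome"] = -flipped["outcome"]
        r2 = pgs_by_e_test(fitted["gw_score"], flipped, covariates)
        assert r2.beta_int == pytest.approx(-r1.beta_int, abs=1e-12)
        assert r2.p == pytest.approx(r1.p, rel=1e-9)

    def test_constant_score_rejected(self, signal_dataset, covariates):
        s = ScoreVector("c", np.ones(len(signal_dataset["pheno"])), np.ones(len(signal_dataset["pheno"])), 1)
        with pytest.raises(DesignError, match="constant"):
            pgs_by_e_test(s, signal_dataset["pheno"], covariates)

    def test_missing_covariate_named(self, signal_dataset, covariates):
        pheno = signal_dataset["pheno"].drop(columns=["gpc_3"])
        with pytest.raises(DesignError, match="gpc_3"):
            pgs_by_e_test(score_from(pheno["outcome"]), pheno, covariates)

    def test_exposure_shift_invariance(self, signal_dataset, covariates, fitted):
        """Adding a constant to the exposure before re-standardization leaves
        the interaction estimate unchanged."""
        d = signal_dataset
        r1 = pgs_by_e_test(fitted["gw_score"], d["pheno"], covariates)
        shifted = d["pheno"].copy()
        e = shifted["exposure"].to_numpy() + 5.0
        shifted["exposure"] = (e - e.mean()) / e.std()
        r2 = pgs_by_e_test(fitted["gw_score"], shifted, covariates)
        assert r2.beta_int == pytest.approx(r1.beta_int, abs=1e-10)

    def test_detects_simulated_pathway_interaction(self, signal_dataset, covariates, fitted):
        d = signal_dataset
        causal = [s for s in fitted["ppgs_scores"] if s.scope == "PW003"]
        assert causal, "causal pathway should be testable"
        r = pgs_by_e_test(causal[0], d["pheno"], covariates)
        assert r.beta_int > 0 and r.p < 0.01


class TestPpgsScan:
    def test_bonferroni_threshold_exact(self, signal_dataset, covariates, fitted):
        results, bon = run_ppgs_scan(fitted["ppgs_scores"], signal_dataset["pheno"], covariates)
        assert bon * len(fitted["ppgs_scores"]) == pytest.approx(0.05)
        assert all(r.significant == (r.p < bon) for r in results)

    def test_single_pathway_threshold_is_alpha(self, signal_dataset, covariates, fitted):
        _, bon = run_ppgs_scan(fitted["ppgs_scores"][:1], signal_dataset["pheno"], covariates, alpha=0.05)
        assert bon == 0.05

    def test_no_scores_rejected(self, signal_dataset, covariates):
        with pytest.raises(DesignError, match="no testable"):
            run_ppgs_scan([], signal_dataset["pheno"], covariates)


class TestJointLrt:
    def test_no_pathways_statistic_zero(self, signal_dataset, covariates, fitted):
        lrt = joint_lrt([], fitted["gw_score"], signal_dataset["pheno"], covariates)
        assert lrt.statistic == 0.0 and lrt.p == 1.0 and lrt.df == 0

    def test_statistic_nonnegative_and_df_counts_terms(self, signal_dataset, covariates, fitted):
        lrt = joint_lrt(fitted["ppgs_scores"], fitted["gw_score"], signal_dataset["pheno"], covariates)
        assert lrt.statistic >= 0
        assert lrt.df == len(fitted["ppgs_scores"]) - len(
            [t for t in lrt.dropped_terms if t.startswith("int::")]
        )

    def test_detects_causal_pathway_architecture(self, signal_dataset, covariates, fitted):
        lrt = joint_lrt(fitted["ppgs_scores"], fitted["gw_score"], signal_dataset["pheno"], covariates)
        assert lrt.p < 0.05

    def test_aliased_duplicate_score_dropped(self, signal_dataset, covariates, fitted):
        dup = ScoreVector(
            scope="DUPLICATE",
            raw=fitted["ppgs_scores"][0].raw.copy(),
            standardized=fitted["ppgs_scores"][0].standardized.copy(),
            n_variants=fitted["ppgs_scores"][0].n_variants,
        )
        lrt = joint_lrt(
            fitted["ppgs_scores"] + [dup], fitted["gw_score"], signal_dataset["pheno"], covariates
        )
        assert any("DUPLICATE" in t or fitted["ppgs_scores"][0].scope in t for t in lrt.dropped_terms)
        assert lrt.df == len(fitted["ppgs_scores"])

    def test_deviance_additivity_over_nested_path(self, signal_dataset, covariates, fitted):
        """The joint statistic equals the sum of single-term drops when
        interaction terms are added one at a time (nested Gaussian OLS)."""
        scores = fitted["ppgs_scores"][:3]
        full = joint_lrt(scores, fitted["gw_score"], signal_dataset["pheno"], covariates)
        # add interaction terms one at a time via nested reduced models
        from ppgs_gxe.interaction import _interaction_design
        from ppgs_gxe.assoc import ols_fit

        d = signal_dataset
        e = d["pheno"]["exposure"].to_numpy()
        y = d["pheno"]["outcome"].to_numpy()
        X = _interaction_design(fitted["gw_score"].standardized, d["pheno"], covariates, "exposure")
        X = X.rename(columns={"score": "gw", "score_by_exposure": "gwxe"})
        for s in scores:
            X[f"main_{s.scope}"] = s.standardized
        lls = [ols_fit(X, y).loglik]
        for s in scores:
            X[f"int_{s.scope}"] = s.standardized * e
            lls.append(ols_fit(X, y).loglik)
        stepwise = 2 * (lls[-1] - lls[0])
        assert full.statistic == pytest.approx(stepwise, abs=1e-6)

    def test_mains_in_full_only_variant(self, signal_dataset, covariates, fitted):
        scores = fitted["ppgs_scores"][:4]
        lrt = joint_lrt(
            scores, fitted["gw_score"], signal_dataset["pheno"], covariates, mains_in_reduced=False
        )
        assert lrt.df == 2 * len(scores)


class TestSensitivity:
    def test_adjustment_changes_estimate_minimally_when_exposure_not_heritable(
        self, signal_dataset, covariates, fitted
    ):
        d = signal_dataset  # exposure_h2 = 0 in this cohort
        rng = np.random.default_rng(31)
        fake_exposure_pgs = score_from(rng.standard_normal(len(d["pheno"])), "exposure_pgs")
        base = pgs_by_e_test(fitted["gw_score"], d["pheno"], covariates)
        adj = sensitivity_exposure_pgs(fitted["gw_score"], d["pheno"], covariates, fake_exposure_pgs)
        assert adj.beta_int == pytest.approx(base.beta_int, abs=0.01)

    def test_adjusted_estimate_within_2se_when_exposure_heritable(self, covariates):
        sim = SimulationConfig(
            n_samples=4000, n_variants=300, n_genes=60, n_pathways=10,
            causal_pathways=("PW002",), beta_main_sd=0.1, beta_main_sd_causal=0.25,
            alpha_interaction_sd=0.06, exposure_h2=0.3, seed=71,
        )
        d = make_dataset(sim)
        ss = gwas_main(d["genotypes"], d["pheno"], covariates)
        gw = build_gwpgs(ss, d["genotypes"], ClumpConfig())
        gw_score = compute_score(d["genotypes"], gw)
        # exposure PGS from a GWAS of the exposure itself
        ss_exp = gwas_main(d["genotypes"], d["pheno"], covariates, outcome_col="exposure")
        exp_w = build_gwpgs(ss_exp, d["genotypes"], ClumpConfig(), p_threshold=0.05)
        exp_score = compute_score(d["genotypes"], exp_w)
        base = pgs_by_e_test(gw_score, d["pheno"], covariates)
        for mode in ("main_only", "main_plus_interaction"):
            adj = sensitivity_exposure_pgs(gw_score, d["pheno"], covariates, exp_score, mode=mode)
            assert abs(adj.beta_int - base.beta_int) < 2 * base.se

    def test_exposure_pgs_identical_to_focal_score_collinear(self, signal_dataset, covariates, fitted):
        with pytest.raises(DesignError):
            sensitivity_exposure_pgs(
                fitted["gw_score"], signal_dataset["pheno"], covariates, fitted["gw_score"]
            )

    def test_unknown_mode_rejected(self, signal_dataset, covariates, fitted):
        with pytest.raises(ValueError, match="mode"):
            sensitivity_exposure_pgs(
                fitted["gw_score"], signal_dataset["pheno"], covariates, fitted["gw_score"], mode="x"
            )


class TestSplitSample:
    def test_deterministic_split(self, signal_dataset, covariates, clump_config):
        d = signal_dataset
        kwargs = dict(
            pathway_variants=d["pv_sets"], covariates=covariates, clump_config=clump_config,
            test_fraction=0.3, seed=5,
        )
        r1 = split_sample_eval(d["genotypes"], d["pheno"], **kwargs)
        r2 = split_sample_eval(d["genotypes"], d["pheno"], **kwargs)
        pd.testing.assert_frame_equal(r1.per_pathway, r2.per_pathway)
        assert r1.n_test == round(0.3 * d["genotypes"].n_samples)

    def test_too_small_test_split_rejected(self, signal_dataset, covariates, clump_config):
        d = signal_dataset
        with pytest.raises(ValueError, match="too small"):
            split_sample_eval(
                d["genotypes"], d["pheno"], d["pv_sets"], covariates, clump_config,
                test_fraction=0.01, seed=1,
            )

    def test_concordance_under_strong_architecture(self, covariates, clump_config):
        sim = SimulationConfig(
            n_samples=8000, n_variants=400, n_genes=80, n_pathways=15,
            causal_pathways=("PW002", "PW007"), beta_main_sd=0.12, beta_main_sd_causal=0.3,
            alpha_interaction_sd=0.08, seed=81,
        )
        d = make_dataset(sim)
        res = split_sample_eval(
            d["genotypes"], d["pheno"], d["pv_sets"], covariates, clump_config,
            test_fraction=0.2, seed=3,
        )
        assert len(res.per_pathway) >= 5
        assert res.correlation > 0.8
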