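"""PGS×E interaction testing, Bonferroni scan, joint LRTs, sensitivity checks.

Every test fits, by Gaussian OLS,

    outcome ~ score + exposure + score×exposure
              + age + age² + sex + age×sex + gPCs + exposure×gPCs

and reports the score×exposure coefficient on the standardized scale
(SD outcome per SD score per SD exposure). Model-based standard errors are the
default for the PGS-level tests (robust available); the joint LRT compares
nested Gaussian maximum-likelihood fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as scipy_qr

from .assoc import DesignError, build_covariate_matrix, ols_fit
from .config import ClumpConfig, CovariateSpec
from .containers import GenotypeMatrix, InteractionResult, LrtResult, ScoreVector


def _interaction_design(
    score: np.ndarray,
    pheno: pd.DataFrame,
    covariates: CovariateSpec,
    exposure_col: str,
    extra: Optional[dict[str, np.ndarray]] = None,
) -> pd.DataFrame:
    if np.asarray(score).std() == 0:
        raise DesignError("score is constant; interaction model undefined")
    Z = build_covariate_matrix(pheno, covariates, exposure_col=exposure_col)
    e = pheno[exposure_col].to_numpy(dtype=float)
    X = pd.DataFrame({"const": np.ones(len(pheno)), "score": score})
    X["score_by_exposure"] = score * e
    for col in Z.columns:
        X[col] = Z[col].to_numpy()
    if extra:
        for name, vals in extra.items():
            X[name] = vals
    return X


def pgs_by_e_test(
    score: ScoreVector,
    pheno: pd.DataFrame,
    covariates: CovariateSpec,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    robust: Optional[str] = None,
    threshold: Optional[float] = None,
    extra_terms: Optional[dict[str, np.ndarray]] = None,
) -> InteractionResult:
    """Test one (standardized) polygenic score for interaction with the exposure."""
    X = _interaction_design(score.standardized, pheno, covariates, exposure_col, extra_terms)
    fit = ols_fit(X, pheno[outcome_col].to_numpy(dtype=float), robust=robust)
    beta, se, p = fit.term("score_by_exposure")
    return InteractionResult(
        scope=score.scope,
        beta_int=beta,
        se=se,
        p=p,
        n=fit.n,
        significant=None if threshold is None else bool(p < threshold),
        threshold=threshold,
        model_terms=fit.terms,
        robust=robust is not None,
        loglik=fit.loglik,
    )


def run_ppgs_scan(
    scores: Sequence[ScoreVector],
    pheno: pd.DataFrame,
    covariates: CovariateSpec,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    alpha: float = 0.05,
    robust: Optional[str] = None,
) -> tuple[list[InteractionResult], float]:
    """One pgs_by_e_test per pathway score under Bonferroni correction.

    The threshold is alpha divided by the number of pathways actually tested
    (pathways excluded upstream for having too few variants do not count).
    """
    if not scores:
        raise DesignError("no testable pathway scores supplied")
    bonferroni = alpha / len(scores)
    results = [
        pgs_by_e_test(
            s, pheno, covariates, exposure_col, outcome_col, robust=robust, threshold=bonferroni
        )
        for s in scores
    ]
    return results, bonferroni


def interaction_results_frame(results: Sequence[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scope": [r.scope for r in results],
            "beta_int": [r.beta_int for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "significant": [r.significant for r in results],
            "threshold": [r.threshold for r in results],
        }
    )


def _drop_aliased(X: pd.DataFrame, protect: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Drop aliased (rank-deficient) columns by pivoted QR, never a protected one."""
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    _, R, piv = scipy_qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    dropped = [X.columns[i] for i in piv[rank:]]
    bad_protected = [c for c in dropped if c in set(protect)]
    if bad_protected:
        raise DesignError(f"core model columns are collinear: {bad_protected}")
    return X.drop(columns=dropped), dropped


def joint_lrt(
    pathway_scores: Sequence[ScoreVector],
    gw_score: ScoreVector,
    pheno: pd.DataFrame,
    covariates: CovariateSpec,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    mains_in_reduced: bool = True,
) -> LrtResult:
    """Do all pathway-score interactions jointly improve on the genome-wide one?

    Reduced model: covariates + exposure + gwPGS + gwPGS×exposure (+ all
    pathway-score main effects when ``mains_in_reduced``, the default, so the
    test isolates the interaction terms). Full model adds one score×exposure
    term per pathway. Aliased score columns are dropped (reported) and the
    degrees of freedom are the retained interaction terms. Gaussian ML
    likelihoods; χ² p-value.
    """
    e = pheno[exposure_col].to_numpy(dtype=float)
    y = pheno[outcome_col].to_numpy(dtype=float)
    base = _interaction_design(gw_score.standardized, pheno, covariates, exposure_col)
    base = base.rename(columns={"score": "gwpgs", "score_by_exposure": "gwpgs_by_exposure"})

    full = base.copy()
    for s in pathway_scores:
        full[f"main::{s.scope}"] = s.standardized
    for s in pathway_scores:
        full[f"int::{s.scope}"] = s.standardized * e
    protect = [c for c in base.columns]
    # pivoted QR keeps one representative of any aliased group (duplicated or
    # otherwise collinear pathway scores) and reports the rest by name
    full, dropped = _drop_aliased(full, protect=protect)

    int_cols = [c for c in full.columns if c.startswith("int::")]
    reduced_cols = [c for c in full.columns if not c.startswith("int::")]
    if not mains_in_reduced:
        reduced_cols = [c for c in reduced_cols if not c.startswith("main::")]

    fit_full = ols_fit(full, y)
    fit_reduced = ols_fit(full[reduced_cols], y)
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    df = len(int_cols) + (0 if mains_in_reduced else len([c for c in full.columns if c.startswith("main::")]))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LrtResult(
        loglik_full=fit_full.loglik,
        loglik_reduced=fit_reduced.loglik,
        statistic=stat,
        df=df,
        p=p,
        dropped_terms=sorted(dropped),
    )


def sensitivity_exposure_pgs(
    score: ScoreVector,
    pheno: pd.DataFrame,
    covariates: CovariateSpec,
    exposure_pgs: ScoreVector,
    mode: str = "main_only",
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
) -> InteractionResult:
    """Re-test the focal interaction adjusting for a PGS of the exposure.

    Guards against the focal score merely tracking the exposure's own
    genetics. ``mode`` is 'main_only' (adds the exposure PGS main effect) or
    'main_plus_interaction' (also its product with the exposure).
    """
    if mode not in ("main_only", "main_plus_interaction"):
        raise ValueError(f"unknown mode {mode!r}")
    e = pheno[exposure_col].to_numpy(dtype=float)
    extra = {"exposure_pgs": exposure_pgs.standardized}
    if mode == "main_plus_interaction":
        extra["exposure_pgs_by_exposure"] = exposure_pgs.standardized * e
    return pgs_by_e_test(
        score, pheno, covariates, exposure_col, outcome_col, extra_terms=extra
    )


@dataclass
class SplitSampleResult:
    """Held-out comparison of training-derived vs full-data-derived weights."""

    per_pathway: pd.DataFrame  # scope, beta_train, se_train, p_train, beta_full, se_full, p_full
    correlation: float
    n_train: int
    n_test: int


def split_sample_eval(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    pathway_variants,
    covariates: CovariateSpec,
    clump_config: ClumpConfig,
    p_threshold: float = 0.001,
    test_fraction: float = 0.2,
    seed: int = 0,
    min_variants: int = 2,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
) -> SplitSampleResult:
    """Re-derive P&T weights on a training split and test in the held-out split.

    Both training-derived and full-data-derived pathway weights are scored and
    tested for interaction in the same held-out fraction; the paired
    per-pathway interaction estimates and their Pearson correlation quantify
    how much same-sample training matters.
    """
    from .assoc import gwas_main
    from .pgs import build_gwpgs, build_ppgs, compute_score

    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0, 1): {test_fraction}")
    n = genotypes.n_samples
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(17,))))
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    model_df = 6 + 2 * covariates.n_gpcs
    if n_test < 2 * model_df:
        raise ValueError(f"test split of {n_test} samples is too small for a {model_df}-parameter model")

    geno_train = genotypes.subset_samples(train_idx)
    geno_test = genotypes.subset_samples(test_idx)
    pheno_train = pheno.iloc[train_idx].reset_index(drop=True)
    pheno_test = pheno.iloc[test_idx].reset_index(drop=True)

    rows = []
    results: dict[str, dict[str, InteractionResult]] = {}
    for label, geno_fit, pheno_fit in (
        ("train", geno_train, pheno_train),
        ("full", genotypes, pheno),
    ):
        ss = gwas_main(geno_fit, pheno_fit, covariates, outcome_col=outcome_col)
        gw = build_gwpgs(ss, geno_fit, clump_config, p_threshold)
        ppgs, _ = build_ppgs(gw, pathway_variants, ss, min_variants=min_variants)
        for w in ppgs:
            score = compute_score(geno_test, w)
            res = pgs_by_e_test(score, pheno_test, covariates, exposure_col, outcome_col)
            results.setdefault(w.scope, {})[label] = res

    for scope, pair in sorted(results.items()):
        if "train" in pair and "full" in pair:
            rows.append(
                {
                    "scope": scope,
                    "beta_train": pair["train"].beta_int,
                    "se_train": pair["train"].se,
                    "p_train": pair["train"].p,
                    "beta_full": pair["full"].beta_int,
                    "se_full": pair["full"].se,
                    "p_full": pair["full"].p,
                }
            )
    per_pathway = pd.DataFrame(rows)
    if len(per_pathway) >= 2:
        corr = float(np.corrcoef(per_pathway["beta_train"], per_pathway["beta_full"])[0, 1])
    else:
        corr = float("nan")
    return SplitSampleResult(
        per_pathway=per_pathway,
        correlation=corr,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )
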