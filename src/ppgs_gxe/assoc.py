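"""Core regression machinery: OLS with sandwich covariance, GWAS, and GWIS.

The main-effect scan residualizes the outcome and every dosage column on the
shared covariates once (Frisch–Waugh–Lovell), which reproduces per-variant
full refits exactly. The interaction scan refits per variant because the
heteroskedasticity-robust sandwich does not commute with projection; robust
standard errors default to HC3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CovariateSpec
from .containers import GenotypeMatrix

SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "term",
    "beta",
    "se",
    "robust",
    "p",
    "n",
    "flag",
]

_ROBUST_FLAVORS = ("hc0", "hc1", "hc3")


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable design matrices."""


@dataclass
class OLSResult:
    """Least-squares fit with model-based or sandwich covariance."""

    terms: list[str]
    params: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    n: int
    df_resid: int
    rss: float
    robust: Optional[str] = None
    residuals: np.ndarray = field(default=None, repr=False)

    def term(self, name: str) -> tuple[float, float, float]:
        i = self.terms.index(name)
        return float(self.params[i]), float(self.se[i]), float(self.p[i])


def gaussian_loglik(rss: float, n: int) -> float:
    """Gaussian maximum-likelihood log-likelihood at the OLS solution."""
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def ols_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    robust: Optional[str] = None,
    terms: Optional[Sequence[str]] = None,
) -> OLSResult:
    """Fit y = Xb + e by least squares.

    ``robust`` selects the sandwich flavor ('hc0', 'hc1', 'hc3') or None for
    the model-based covariance. p-values use the t distribution with
    residual degrees of freedom. Raises :class:`DesignError` for
    rank-deficient designs (naming the collinear columns) and when n <= p.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns) if terms is None else list(terms)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if terms is None:
            terms = [f"x{i}" for i in range(X.shape[1])]
        terms = list(terms)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DesignError(f"n ({n}) must exceed number of parameters ({p})")
    if robust is not None and robust.lower() not in _ROBUST_FLAVORS:
        raise DesignError(f"unknown robust flavor {robust!r}; expected one of {_ROBUST_FLAVORS}")

    # rank check; on deficiency, pivoted QR names the offending columns
    Q, R = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if np.any(diag <= tol):
        from scipy.linalg import qr as scipy_qr

        _, Rp, piv = scipy_qr(X, mode="economic", pivoting=True)
        dg = np.abs(np.diag(Rp))
        rank = int(np.sum(dg > max(n, p) * np.finfo(float).eps * dg.max()))
        bad = [terms[i] for i in piv[rank:]]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")

    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    Rinv = np.linalg.solve(R, np.eye(p))
    XtX_inv = Rinv @ Rinv.T

    if robust is None:
        cov = (rss / df) * XtX_inv
        used = None
    else:
        flavor = robust.lower()
        if flavor == "hc3":
            h = np.einsum("ij,ij->i", Q, Q)
            w = (resid / (1.0 - h)) ** 2
        elif flavor == "hc1":
            w = resid**2 * (n / df)
        else:  # hc0
            w = resid**2
        XtWX = (X * w[:, None]).T @ X
        cov = XtX_inv @ XtWX @ XtX_inv
        used = flavor

    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return OLSResult(
        terms=terms,
        params=beta,
        se=se,
        p=pvals,
        loglik=gaussian_loglik(rss, n),
        n=n,
        df_resid=df,
        rss=rss,
        robust=used,
        residuals=resid,
    )


def build_covariate_matrix(
    pheno: pd.DataFrame,
    covariates: CovariateSpec,
    exposure_col: Optional[str] = None,
) -> pd.DataFrame:
    """Expand the covariate specification against a phenotype table.

    With ``exposure_col`` given, exposure and exposure×gPC product terms are
    included (the interaction-model adjustment set); without it, the
    main-effect adjustment set is returned. Raises if any required column is
    missing.
    """
    cols: dict[str, np.ndarray] = {}
    need = []
    if covariates.age or covariates.age_squared or covariates.age_by_sex:
        need.append("age")
    if covariates.sex or covariates.age_by_sex:
        need.append("sex")
    need.extend(f"gpc_{k + 1}" for k in range(covariates.n_gpcs))
    if exposure_col is not None:
        need.append(exposure_col)
    missing = [c for c in need if c not in pheno.columns]
    if missing:
        raise DesignError(f"phenotype table missing covariate columns: {missing}")

    if covariates.age:
        cols["age"] = pheno["age"].to_numpy(dtype=float)
    if covariates.age_squared:
        cols["age_sq"] = pheno["age"].to_numpy(dtype=float) ** 2
    if covariates.sex:
        cols["sex"] = pheno["sex"].to_numpy(dtype=float)
    if covariates.age_by_sex:
        cols["age_by_sex"] = pheno["age"].to_numpy(dtype=float) * pheno["sex"].to_numpy(dtype=float)
    for k in range(covariates.n_gpcs):
        cols[f"gpc_{k + 1}"] = pheno[f"gpc_{k + 1}"].to_numpy(dtype=float)
    if exposure_col is not None:
        e = pheno[exposure_col].to_numpy(dtype=float)
        cols["exposure"] = e
        if covariates.exposure_by_gpcs:
            for k in range(covariates.n_gpcs):
                cols[f"exposure_by_gpc_{k + 1}"] = e * cols[f"gpc_{k + 1}"]
    out = pd.DataFrame(cols)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise DesignError(f"missing values in covariates: {bad}")
    return out


def _summary_frame(genotypes: GenotypeMatrix, term: str, robust: bool, n: int) -> pd.DataFrame:
    var = genotypes.variants
    return pd.DataFrame(
        {
            "variant_id": var["variant_id"],
            "chrom": var["chrom"].astype(str),
            "pos": var["pos"].astype(int),
            "effect_allele": var["alt"],
            "term": term,
            "beta": np.nan,
            "se": np.nan,
            "robust": robust,
            "p": np.nan,
            "n": n,
            "flag": "",
        }
    )


def gwas_main(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariates: CovariateSpec,
    outcome_col: str = "outcome",
) -> pd.DataFrame:
    """Per-variant main-effect scan: outcome ~ dosage + covariates.

    Missing dosages are mean-imputed per variant; effects are reported for
    the alt allele. Monomorphic variants are emitted with p = 1 and a flag.
    Implemented by residualizing outcome and dosages on the covariates once;
    this matches per-variant full refits exactly.
    """
    y = pheno[outcome_col].to_numpy(dtype=float)
    Z = build_covariate_matrix(pheno, covariates, exposure_col=None)
    Zm = np.column_stack([np.ones(len(pheno)), Z.to_numpy(dtype=float)])
    n, k = Zm.shape
    Q, _ = np.linalg.qr(Zm)
    G = genotypes.imputed()
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    yy = float(y_res @ y_res)
    df = n - k - 1

    out = _summary_frame(genotypes, "main", robust=False, n=n)
    mono = gg <= n * 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, 0.0, gy / np.where(mono, 1.0, gg))
        rss = yy - beta**2 * gg
        se = np.sqrt(np.maximum(rss, 0.0) / df / np.where(mono, 1.0, gg))
        tvals = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tvals), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out["beta"] = np.where(mono, 0.0, beta)
    out["se"] = np.where(mono, np.nan, se)
    out["p"] = np.where(mono, 1.0, p)
    out.loc[mono, "flag"] = "monomorphic"
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def gwis_interaction(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariates: CovariateSpec,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    robust: Optional[str] = "hc3",
) -> pd.DataFrame:
    """Per-variant interaction scan with robust standard errors.

    Model: outcome ~ dosage + exposure + dosage×exposure + covariates +
    exposure×gPC terms; the reported term is dosage×exposure. Each variant is
    a full refit (sandwich covariance is not projection-invariant). Variants
    with zero variance in dosage or in the product term are flagged with
    p = 1, never dropped.
    """
    y = pheno[outcome_col].to_numpy(dtype=float)
    e = pheno[exposure_col].to_numpy(dtype=float)
    if np.allclose(e.var(), 0.0):
        raise DesignError(f"exposure column {exposure_col!r} is constant; interaction term degenerate")
    Z = build_covariate_matrix(pheno, covariates, exposure_col=exposure_col)
    n = len(pheno)
    Zm = np.column_stack([np.ones(n), Z.to_numpy(dtype=float)])
    k = Zm.shape[1]
    G = genotypes.imputed()

    X = np.empty((n, k + 2))
    X[:, :k] = Zm
    out = _summary_frame(genotypes, "interaction", robust=robust is not None, n=n)
    betas = np.full(genotypes.n_variants, np.nan)
    ses = np.full(genotypes.n_variants, np.nan)
    ps = np.full(genotypes.n_variants, np.nan)
    flags = [""] * genotypes.n_variants

    flavor = robust.lower() if robust is not None else None
    if flavor is not None and flavor not in _ROBUST_FLAVORS:
        raise DesignError(f"unknown robust flavor {robust!r}")

    for j in range(genotypes.n_variants):
        g = G[:, j]
        ge = g * e
        if g.var() <= 1e-12 or ge.var() <= 1e-12:
            betas[j], ses[j], ps[j] = 0.0, np.nan, 1.0
            flags[j] = "degenerate_interaction"
            continue
        X[:, k] = g
        X[:, k + 1] = ge
        XtX = X.T @ X
        Xty = X.T @ y
        try:
            beta = np.linalg.solve(XtX, Xty)
        except np.linalg.LinAlgError:
            betas[j], ses[j], ps[j] = 0.0, np.nan, 1.0
            flags[j] = "singular_fit"
            continue
        resid = y - X @ beta
        df = n - (k + 2)
        XtX_inv = np.linalg.inv(XtX)
        if flavor is None:
            var_int = (resid @ resid) / df * XtX_inv[k + 1, k + 1]
        else:
            if flavor == "hc3":
                B = X @ XtX_inv
                h = np.einsum("ij,ij->i", B, X)
                w = (resid / (1.0 - h)) ** 2
            elif flavor == "hc1":
                w = resid**2 * (n / df)
            else:
                w = resid**2
            a = XtX_inv[:, k + 1]
            xa = X @ a
            var_int = float((xa * w) @ xa)
        se = np.sqrt(var_int)
        t = beta[k + 1] / se
        betas[j] = beta[k + 1]
        ses[j] = se
        ps[j] = max(2.0 * stats.t.sf(abs(t), df), np.finfo(float).tiny)

    out["beta"] = betas
    out["se"] = ses
    out["p"] = ps
    out["flag"] = flags
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_summary_stats(stats_df: pd.DataFrame, path) -> None:
    stats_df.to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
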