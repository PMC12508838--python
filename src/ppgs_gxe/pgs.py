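"""Pruning-and-thresholding polygenic scores, genome-wide and pathway-restricted.

Construction follows the PRSet convention: greedy LD clumping of the full
summary statistics (index variants by ascending p; neighbors within the
physical window removed at r² ≥ threshold), p-value thresholding (strict),
then — for pathway scores — restriction of the surviving genome-wide set to
each pathway's variant set. In-sample genotypes are the LD source and scores
are standardized in sample.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import PathwayVariantSets
from .config import ClumpConfig
from .containers import GenotypeMatrix, PGSWeights, ScoreVector


class ScoreError(ValueError):
    """Raised when a score cannot be built (no variants, constant score...)."""


def clump(
    sumstats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: ClumpConfig,
) -> list[str]:
    """Greedy LD clumping; returns retained variant ids in selection order.

    Repeatedly takes the unremoved variant with the smallest p (ties broken
    by smaller position, then lexicographic id), retains it, and removes all
    unretained variants on the same chromosome within ``window_kb`` whose
    dosage r² with it is at least ``r2_threshold``. Only variants with
    p < ``p_index_max`` participate.
    """
    shared = sumstats[sumstats["variant_id"].isin(set(genotypes.variant_ids))]
    shared = shared[shared["p"] < config.p_index_max]
    if shared.empty:
        warnings.warn("clump: no variants shared between summary stats and genotypes")
        return []
    order = shared.sort_values(["p", "pos", "variant_id"], kind="mergesort")

    cols = genotypes.column_index(order["variant_id"].tolist())
    G = genotypes.imputed(cols)
    G = G - G.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", G, G))
    norms[norms == 0] = np.inf
    Gn = G / norms

    chroms = order["chrom"].astype(str).to_numpy()
    pos = order["pos"].to_numpy(dtype=float)
    ids = order["variant_id"].to_numpy()
    window_bp = config.window_kb * 1000.0

    n_v = len(ids)
    # one gemm for all pairwise correlations is much faster than per-index
    # slicing at scan sizes; fall back to per-index products on huge panels
    C = Gn.T @ Gn if n_v <= 4000 else None

    removed = np.zeros(n_v, dtype=bool)
    retained: list[str] = []
    for i in range(n_v):
        if removed[i]:
            continue
        retained.append(ids[i])
        removed[i] = True  # mark processed; it is retained, not removable
        near = np.where(
            (~removed)
            & (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )[0]
        if near.size:
            r = C[near, i] if C is not None else Gn[:, near].T @ Gn[:, i]
            removed[near[r**2 >= config.r2_threshold]] = True
    return retained


def threshold(sumstats: pd.DataFrame, p_threshold: float = 0.001) -> list[str]:
    """Variant ids with p strictly below the threshold."""
    keep = sumstats.loc[sumstats["p"] < p_threshold, "variant_id"]
    return keep.tolist()


def build_gwpgs(
    sumstats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    clump_config: ClumpConfig,
    p_threshold: float = 0.001,
) -> PGSWeights:
    """Genome-wide P&T weights: GWAS betas of clumped ∩ thresholded variants."""
    below = set(threshold(sumstats, p_threshold))
    surviving = [v for v in clump(sumstats, genotypes, clump_config) if v in below]
    if not surviving:
        raise ScoreError(f"no variants survive clumping at p < {p_threshold}; genome-wide score undefined")
    ss = sumstats.set_index("variant_id")
    return PGSWeights(
        scope="genome_wide",
        variant_ids=surviving,
        effect_alleles=[ss.at[v, "effect_allele"] for v in surviving],
        weights=np.array([ss.at[v, "beta"] for v in surviving], dtype=float),
        p_threshold=p_threshold,
    )


def build_ppgs(
    gw_weights: PGSWeights,
    pathway_variants: PathwayVariantSets,
    sumstats: pd.DataFrame,
    min_variants: int = 2,
) -> tuple[list[PGSWeights], list[str]]:
    """Pathway scores: genome-wide surviving weights restricted per pathway.

    Pathways with fewer than ``min_variants`` surviving variants are excluded
    from testing and returned in the second element.
    """
    gw_index = {v: i for i, v in enumerate(gw_weights.variant_ids)}
    out: list[PGSWeights] = []
    excluded: list[str] = []
    for pid in pathway_variants:
        members = [v for v in gw_weights.variant_ids if v in pathway_variants[pid]]
        if len(members) < min_variants:
            excluded.append(pid)
            continue
        idx = [gw_index[v] for v in members]
        out.append(
            PGSWeights(
                scope=pid,
                variant_ids=members,
                effect_alleles=[gw_weights.effect_alleles[i] for i in idx],
                weights=np.asarray(gw_weights.weights)[idx].copy(),
                p_threshold=gw_weights.p_threshold,
            )
        )
    return out, excluded


def compute_score(genotypes: GenotypeMatrix, weights: PGSWeights) -> ScoreVector:
    """Additive score Σ_j w_j·g̃_ij (mean-imputed dosages), standardized in sample.

    Effect alleles must equal the genotype alt alleles (allele flipping is out
    of scope for synthetic data); a constant raw score is an error.
    """
    try:
        cols = genotypes.column_index(weights.variant_ids)
    except KeyError as e:
        raise ScoreError(f"weight variant missing from genotypes: {e}")
    alts = genotypes.variants["alt"].to_numpy()
    mismatches = [
        (v, ea, alts[c])
        for v, ea, c in zip(weights.variant_ids, weights.effect_alleles, cols)
        if ea != alts[c]
    ]
    if mismatches:
        raise ScoreError(f"effect allele mismatch for {len(mismatches)} variants, e.g. {mismatches[0]}")
    G = genotypes.imputed(cols)
    raw = G @ np.asarray(weights.weights, dtype=float)
    sd = raw.std()
    if sd == 0:
        raise ScoreError(f"score {weights.scope!r} is constant; cannot standardize")
    return ScoreVector(
        scope=weights.scope,
        raw=raw,
        standardized=(raw - raw.mean()) / sd,
        n_variants=weights.n_variants,
        samples=list(genotypes.samples),
    )


def weights_to_frame(all_weights: Sequence[PGSWeights]) -> pd.DataFrame:
    return pd.concat([w.to_frame() for w in all_weights], ignore_index=True)


def scores_to_frame(scores: Sequence[ScoreVector]) -> pd.DataFrame:
    frames = []
    for s in scores:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.samples,
                    "scope": s.scope,
                    "raw": s.raw,
                    "standardized": s.standardized,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
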