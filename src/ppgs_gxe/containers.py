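"""Shared in-memory containers for genotype and result data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "maf"]


@dataclass
class GenotypeMatrix:
    """Additive dosages (samples × variants) with per-variant metadata.

    ``dosages`` holds values in [0, 2]; missing entries are NaN. ``variants``
    is a DataFrame with columns variant_id, chrom, pos (1-based), ref, alt,
    maf, row-aligned with the dosage columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    def column_index(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Column positions of the given variant ids (KeyError if absent)."""
        lookup = {v: i for i, v in enumerate(self.variants["variant_id"])}
        return np.array([lookup[v] for v in variant_ids], dtype=int)

    def imputed(self, cols: Optional[np.ndarray] = None) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean."""
        sub = self.dosages if cols is None else self.dosages[:, cols]
        if not np.isnan(sub).any():
            return sub.copy()
        sub = sub.copy()
        col_mean = np.nanmean(sub, axis=0)
        idx = np.where(np.isnan(sub))
        sub[idx] = col_mean[idx[1]]
        return sub

    def subset_samples(self, row_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[row_idx],
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in np.asarray(row_idx)],
        )


@dataclass
class PGSWeights:
    """P&T-surviving variant weights; ``scope`` is 'genome_wide' or a pathway id."""

    scope: str
    variant_ids: list[str]
    effect_alleles: list[str]
    weights: np.ndarray
    p_threshold: float

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scope": self.scope,
                "variant_id": self.variant_ids,
                "effect_allele": self.effect_alleles,
                "weight": np.asarray(self.weights, dtype=float),
            }
        )


@dataclass
class ScoreVector:
    """Per-sample raw and standardized polygenic score."""

    scope: str
    raw: np.ndarray
    standardized: np.ndarray
    n_variants: int
    samples: list[str] = field(default_factory=list)


@dataclass
class InteractionResult:
    """A single PGS×E interaction test.

    ``beta_int`` is on the standardized scale: SD of outcome per SD of score
    per SD of exposure.
    """

    scope: str
    beta_int: float
    se: float
    p: float
    n: int
    significant: Optional[bool] = None
    threshold: Optional[float] = None
    model_terms: list[str] = field(default_factory=list)
    robust: bool = False
    loglik: Optional[float] = None


@dataclass
class LrtResult:
    """Likelihood-ratio test between nested Gaussian OLS models."""

    loglik_full: float
    loglik_reduced: float
    statistic: float
    df: int
    p: float
    dropped_terms: list[str] = field(default_factory=list)


@dataclass
class LocusSet:
    """Lead variants after greedy distance pruning of a significance scan."""

    leads: pd.DataFrame  # variant_id, chrom, pos, beta, p
    window_kb: float
    p_threshold: float

    @property
    def n_loci(self) -> int:
        return len(self.leads)
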