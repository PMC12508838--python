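"""GWIS locus pruning, explained/unexplained pathway overlap, effective counts.

A significant pathway interaction is "explained" if at least one GWIS lead
variant lies within a TSS window (default ±100 kb, inclusive) of any gene in
the pathway; pathways with no nearby lead are the discoveries a single-variant
scan would have missed. Because pathway scores are correlated, the raw count
of significant pathways overstates the number of independent discoveries; an
eigenvalue-based effective count over the score correlation matrix corrects
for this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import PathwayCollection
from .containers import LocusSet


def prune_loci(
    sumstats: pd.DataFrame,
    p_threshold: float = 5e-8,
    window_kb: float = 500.0,
) -> LocusSet:
    """Greedy distance-based pruning of a significance scan to lead variants.

    The smallest-p significant variant (ties: smaller position, then
    lexicographic id) is retained as a lead and all significant variants
    within ±``window_kb`` on the same chromosome are removed; repeat until
    exhausted. An empty result is valid.
    """
    sig = sumstats[sumstats["p"] < p_threshold]
    sig = sig.sort_values(["p", "pos", "variant_id"], kind="mergesort").reset_index(drop=True)
    chroms = sig["chrom"].astype(str).to_numpy()
    pos = sig["pos"].to_numpy(dtype=float)
    window_bp = window_kb * 1000.0

    removed = np.zeros(len(sig), dtype=bool)
    lead_rows = []
    for i in range(len(sig)):
        if removed[i]:
            continue
        lead_rows.append(i)
        removed[(chroms == chroms[i]) & (np.abs(pos - pos[i]) <= window_bp)] = True
    leads = sig.iloc[lead_rows][["variant_id", "chrom", "pos", "beta", "p"]].reset_index(drop=True)
    return LocusSet(leads=leads, window_kb=window_kb, p_threshold=p_threshold)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class OverlapTable:
    """Per-pathway explained/unexplained annotation plus the totals row."""

    per_pathway: pd.DataFrame  # pathway_id, explained, explaining_loci, flag
    n_loci: int
    n_significant_pathways: int
    n_unexplained: int
    tss_window_kb: float

    @property
    def fraction_unexplained(self) -> float:
        if self.n_significant_pathways == 0:
            return float("nan")
        return self.n_unexplained / self.n_significant_pathways

    @property
    def percent_unexplained(self) -> Optional[int]:
        if self.n_significant_pathways == 0:
            return None
        return round_half_away(100.0 * self.fraction_unexplained)


def annotate_explained(
    loci: LocusSet,
    significant_pathways: PathwayCollection,
    genes: pd.DataFrame,
    tss_window_kb: float = 100.0,
) -> OverlapTable:
    """Mark each significant pathway as explained/unexplained by GWIS leads.

    A pathway is explained iff some lead variant sits within
    ``tss_window_kb`` (inclusive) of the strand-aware TSS of any member gene
    on the same chromosome. Pathways with no genes in the gene table are
    unexplained and flagged.
    """
    window_bp = tss_window_kb * 1000.0
    gene_info = genes.set_index("gene_id")
    rows = []
    n_unexplained = 0
    for pid in significant_pathways:
        member = [g for g in significant_pathways[pid] if g in gene_info.index]
        flag = "" if member else "no_genes_in_model"
        explaining = []
        for g in member:
            g_chrom = str(gene_info.at[g, "chrom"])
            g_tss = float(gene_info.at[g, "tss"])
            for _, lead in loci.leads.iterrows():
                if str(lead["chrom"]) == g_chrom and abs(float(lead["pos"]) - g_tss) <= window_bp:
                    explaining.append(str(lead["variant_id"]))
        explained = bool(explaining)
        if not explained:
            n_unexplained += 1
        rows.append(
            {
                "pathway_id": pid,
                "explained": explained,
                "explaining_loci": ",".join(sorted(set(explaining))),
                "flag": flag,
            }
        )
    per_pathway = pd.DataFrame(rows, columns=["pathway_id", "explained", "explaining_loci", "flag"])
    return OverlapTable(
        per_pathway=per_pathway,
        n_loci=loci.n_loci,
        n_significant_pathways=len(significant_pathways),
        n_unexplained=n_unexplained,
        tss_window_kb=tss_window_kb,
    )


def effective_n_pathways(
    score_matrix: np.ndarray,
    method: str = "participation_ratio",
) -> float:
    """Correlation-adjusted count of discovered pathways.

    ``score_matrix`` holds one standardized pathway score per column (samples
    × pathways). Both methods operate on the eigenvalues λ of the Pearson
    correlation matrix of the columns:

    * ``participation_ratio``: (Σλ)² / Σλ² — equals K for uncorrelated
      columns and 1 for perfectly correlated ones.
    * ``li_ji``: Li & Ji (2005) count Σ [1(λ≥1) + (λ − ⌊λ⌋)].
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2 or S.shape[1] < 1:
        raise ValueError("score_matrix must be a 2-D samples × pathways array")
    k = S.shape[1]
    if k == 1:
        return 1.0
    corr = np.corrcoef(S, rowvar=False)
    eig = np.linalg.eigvalsh(corr)
    eig = np.clip(eig, 0.0, None)
    if method == "participation_ratio":
        return float(eig.sum() ** 2 / (eig**2).sum())
    if method == "li_ji":
        lam = np.round(eig, 10)  # guard floor() against eigenvalue round-off
        return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    raise ValueError(f"unknown effective-N method {method!r}")


@dataclass
class DiscoveryReport:
    """One overlap-table row per outcome, plus effective pathway counts."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "outcome",
                "n_gwis_loci",
                "n_significant_pathways",
                "n_unexplained",
                "percent_unexplained",
                "effective_n_pathways",
            ]
        )
    )
    effective_n_method: str = "participation_ratio"

    def to_json_dict(self) -> dict:
        return {
            "effective_n_method": self.effective_n_method,
            "rows": self.table.to_dict(orient="records"),
        }


def summarize_discovery(
    loci_by_outcome: dict[str, LocusSet],
    overlap_by_outcome: dict[str, OverlapTable],
    effective_n_by_outcome: dict[str, float],
    effective_n_method: str = "participation_ratio",
) -> DiscoveryReport:
    """Assemble the per-outcome overlap summary (loci / pathways / unexplained)."""
    rows = []
    for outcome in loci_by_outcome:
        overlap = overlap_by_outcome[outcome]
        rows.append(
            {
                "outcome": outcome,
                "n_gwis_loci": loci_by_outcome[outcome].n_loci,
                "n_significant_pathways": overlap.n_significant_pathways,
                "n_unexplained": overlap.n_unexplained,
                "percent_unexplained": overlap.percent_unexplained,
                "effective_n_pathways": effective_n_by_outcome.get(outcome),
            }
        )
    report = DiscoveryReport(effective_n_method=effective_n_method)
    if rows:
        report.table = pd.DataFrame(rows)
    return report
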