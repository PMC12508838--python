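"""Gene sets, gene models, and the variant→gene→pathway mapping.

Variants are assigned to genes by physical distance: a variant maps to a gene
if it falls within the gene body extended 2 kb upstream of the transcription
start site and 1 kb downstream of the transcription end site (strand-aware;
both window parameters configurable). Genes are assigned to pathways by
gene-set membership (GMT files, mSigDB dialect). All coordinates are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes"]


class GmtParseError(ValueError):
    """Raised for malformed GMT input (line number included in the message)."""


@dataclass
class PathwayCollection:
    """Ordered named gene sets: pathway_id → (description, genes)."""

    descriptions: dict[str, str] = field(default_factory=dict)
    genes: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.genes

    def __getitem__(self, pathway_id: str) -> set[str]:
        return self.genes[pathway_id]

    def add(self, pathway_id: str, description: str, genes: Iterable[str]) -> None:
        if pathway_id in self.genes:
            raise GmtParseError(f"duplicate pathway id: {pathway_id}")
        self.descriptions[pathway_id] = description
        self.genes[pathway_id] = set(genes)

    def subset(self, pathway_ids: Iterable[str]) -> "PathwayCollection":
        out = PathwayCollection()
        for pid in pathway_ids:
            out.add(pid, self.descriptions.get(pid, ""), self.genes[pid])
        return out


@dataclass
class VariantGeneMap:
    """variant_id → set of gene ids, with the window parameters that built it."""

    mapping: dict[str, set[str]]
    upstream_bp: int
    downstream_bp: int

    def __getitem__(self, variant_id: str) -> set[str]:
        return self.mapping.get(variant_id, set())

    def genes_to_variants(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for vid, genes in self.mapping.items():
            for g in genes:
                inv.setdefault(g, set()).add(vid)
        return inv


@dataclass
class PathwayVariantSets:
    """pathway_id → set of variant ids (union over member genes)."""

    sets: dict[str, set[str]]
    empty_pathways: list[str]

    def __getitem__(self, pathway_id: str) -> set[str]:
        return self.sets[pathway_id]

    def __iter__(self):
        return iter(self.sets)

    def counts(self) -> dict[str, int]:
        return {pid: len(s) for pid, s in self.sets.items()}


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: one gene set per line, ``id<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated; duplicate pathway ids and
    lines with fewer than three fields are errors.
    """
    collection = PathwayCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected id, description, and at least one gene"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            collection.add(pid, desc, genes)
    return collection


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in collection:
            genes = sorted(collection[pid])
            fh.write("\t".join([pid, collection.descriptions.get(pid, "")] + genes) + "\n")


def gene_window(row: Mapping, upstream_bp: int, downstream_bp: int) -> tuple[int, int]:
    """Genomic (start, end) of the strand-aware extended gene window.

    Upstream extension is applied on the TSS side, downstream on the TES side;
    for minus-strand genes the genomic coordinates mirror accordingly.
    """
    lo = min(row["tss"], row["tes"])
    hi = max(row["tss"], row["tes"])
    if row["strand"] == "+":
        return lo - upstream_bp, hi + downstream_bp
    return lo - downstream_bp, hi + upstream_bp


def map_variants_to_genes(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    upstream_bp: int = 2000,
    downstream_bp: int = 1000,
    closest_only: bool = False,
) -> VariantGeneMap:
    """Assign each variant to the gene(s) whose extended window contains it.

    By default a variant maps to every containing gene window (needed for
    overlapping genes); with ``closest_only`` it maps only to the gene whose
    window midpoint is nearest, ties broken by lexicographic gene id. Variants
    on chromosomes absent from the gene table map to the empty set.
    """
    mapping: dict[str, set[str]] = {}
    trees: dict[str, IntervalTree] = {}
    midpoints: dict[str, float] = {}
    for _, row in genes.iterrows():
        start, end = gene_window(row, upstream_bp, downstream_bp)
        tree = trees.setdefault(str(row["chrom"]), IntervalTree())
        # IntervalTree is half-open; +1 makes [start, end] inclusive
        tree.addi(start, end + 1, row["gene_id"])
        midpoints[row["gene_id"]] = (start + end) / 2.0

    for vid, chrom, pos in zip(variants["variant_id"], variants["chrom"], variants["pos"]):
        tree = trees.get(str(chrom))
        hits = {iv.data for iv in tree.at(int(pos))} if tree is not None else set()
        if closest_only and len(hits) > 1:
            best = min(hits, key=lambda g: (abs(pos - midpoints[g]), g))
            hits = {best}
        mapping[vid] = hits
    return VariantGeneMap(mapping=mapping, upstream_bp=upstream_bp, downstream_bp=downstream_bp)


def build_pathway_variant_sets(
    variant_gene_map: VariantGeneMap, pathways: PathwayCollection
) -> PathwayVariantSets:
    """Union the mapped variants of each pathway's member genes.

    Pathways whose genes carry no mapped variants are retained with empty sets
    and listed in ``empty_pathways``. Membership is non-exclusive: a variant
    near a shared gene appears in every pathway containing that gene.
    """
    gene_to_variants = variant_gene_map.genes_to_variants()
    sets: dict[str, set[str]] = {}
    empty: list[str] = []
    for pid in pathways:
        variants: set[str] = set()
        for gene in pathways[pid]:
            variants |= gene_to_variants.get(gene, set())
        sets[pid] = variants
        if not variants:
            empty.append(pid)
    return PathwayVariantSets(sets=sets, empty_pathways=empty)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    return genes


def read_variant_table(path: str | Path) -> pd.DataFrame:
    variants = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "variant_id" not in variants.columns or "pos" not in variants.columns:
        raise ValueError("variant table must have variant_id and pos columns")
    return variants
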