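"""Readers for externally supplied inputs (dosage TSV, VCF, phenotype TSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


def read_dosage_tsv(path: str | Path, variants: pd.DataFrame) -> GenotypeMatrix:
    """Read a variants × samples dosage TSV (first column variant_id, NA allowed)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "variant_id":
        raise ValueError("dosage TSV must start with a variant_id column")
    df = df.set_index("variant_id")
    order = variants["variant_id"].tolist()
    missing = set(order) - set(df.index)
    if missing:
        raise ValueError(f"dosage TSV missing {len(missing)} variants from the variant table")
    dosages = df.loc[order].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=list(df.columns))


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF, preferring the DS FORMAT field over GT.

    The variant table (variant_id, chrom, pos, ref, alt, maf) is rebuilt from
    the VCF records; MAF is the alt-allele frequency of the read dosages.
    """
    from cyvcf2 import VCF  # heavy import kept local

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        fmt = rec.FORMAT
        if "DS" in fmt:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1)).astype(float)
        ds = np.where(np.isfinite(ds), ds, np.nan)
        maf = float(np.nanmean(ds) / 2.0) if np.isfinite(ds).any() else np.nan
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "maf": maf,
            }
        )
        cols.append(ds)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
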