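"""Shared demo-cohort configuration and result-directory helpers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ppgs_gxe.annotation import read_gene_models, read_gmt, read_variant_table
from ppgs_gxe.config import SimulationConfig
from ppgs_gxe.io import read_dosage_tsv, read_phenotypes

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS / "cohort"

# One synthetic cohort reused by every analysis step: pathway-concentrated
# main and interaction effects in PW003, UKB-like covariates, n = 5000.
DEMO_CONFIG = SimulationConfig(
    n_samples=5000,
    n_variants=500,
    n_genes=100,
    n_pathways=20,
    causal_pathways=("PW003",),
    beta_main_sd=0.1,
    beta_main_sd_causal=0.25,
    alpha_interaction_sd=0.05,
    gamma_exposure=0.1,
    seed=2026,
)


def load_cohort() -> dict:
    """Read the simulated cohort written by 01_simulate_cohort.py."""
    if not COHORT_DIR.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    variants = read_variant_table(COHORT_DIR / "variants.tsv")
    return {
        "genes": read_gene_models(COHORT_DIR / "genes.tsv"),
        "pathways": read_gmt(COHORT_DIR / "pathways.gmt"),
        "variants": variants,
        "genotypes": read_dosage_tsv(COHORT_DIR / "dosages.tsv", variants),
        "pheno": read_phenotypes(COHORT_DIR / "phenotypes.tsv"),
    }
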