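"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ppgs_gxe.annotation import build_pathway_variant_sets, map_variants_to_genes
from ppgs_gxe.config import ClumpConfig, CovariateSpec, SimulationConfig
from ppgs_gxe.synthetic import generate_annotation, simulate_genotypes, simulate_phenotypes


def make_dataset(sim: SimulationConfig) -> dict:
    genes, pathways, variants = generate_annotation(sim)
    genotypes = simulate_genotypes(sim, variants)
    vg_map = map_variants_to_genes(variants, genes)
    pheno, truth = simulate_phenotypes(sim, genotypes, pathways, vg_map)
    return {
        "config": sim,
        "genes": genes,
        "pathways": pathways,
        "variants": variants,
        "genotypes": genotypes,
        "vg_map": vg_map,
        "pv_sets": build_pathway_variant_sets(vg_map, pathways),
        "pheno": pheno,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def covariates() -> CovariateSpec:
    return CovariateSpec()


@pytest.fixture(scope="session")
def clump_config() -> ClumpConfig:
    return ClumpConfig()


@pytest.fixture(scope="session")
def signal_dataset() -> dict:
    """Cohort with pathway-concentrated main and interaction effects."""
    sim = SimulationConfig(
        n_samples=3000,
        n_variants=400,
        n_genes=80,
        n_pathways=20,
        causal_pathways=("PW003",),
        beta_main_sd=0.1,
        beta_main_sd_causal=0.25,
        alpha_interaction_sd=0.05,
        interaction_target_std=0.12,
        seed=101,
    )
    return make_dataset(sim)


@pytest.fixture(scope="session")
def null_dataset() -> dict:
    """Cohort with main effects but no interaction effects anywhere."""
    sim = SimulationConfig(
        n_samples=3000,
        n_variants=400,
        n_genes=80,
        n_pathways=20,
        beta_main_sd=0.1,
        seed=202,
    )
    return make_dataset(sim)


@pytest.fixture(scope="session")
def ld_dataset() -> dict:
    """Larger cohort for LD structure checks (n = 5000)."""
    sim = SimulationConfig(
        n_samples=5000,
        n_variants=300,
        n_genes=60,
        n_pathways=0,
        ld_rho=0.7,
        seed=303,
    )
    return make_dataset(sim)
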