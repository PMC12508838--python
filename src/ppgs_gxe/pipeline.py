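"""End-to-end orchestration: simulate → annotate → GWAS → P&T → scores →
interaction scans → GWIS → locus pruning → overlap → effective-N → LRT →
report, from one validated configuration, with a provenance manifest.

Stage seeds derive from the master seed through named SeedSequence spawn keys
inside the generator; a rerun with an identical config reproduces every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .annotation import build_pathway_variant_sets, map_variants_to_genes
from .assoc import gwas_main, gwis_interaction, write_summary_stats
from .config import ClumpConfig, ConfigError, CovariateSpec, PipelineConfig, SimulationConfig
from .discovery import annotate_explained, effective_n_pathways, prune_loci, summarize_discovery
from .interaction import interaction_results_frame, joint_lrt, pgs_by_e_test, run_ppgs_scan
from .pgs import build_gwpgs, build_ppgs, compute_score, weights_to_frame
from .synthetic import generate_annotation, simulate_genotypes, simulate_phenotypes, write_simulation

logger = logging.getLogger("ppgs_gxe")

STAGES = [
    "simulate",
    "annotate",
    "gwas",
    "pgs",
    "scores",
    "gwpgs_test",
    "ppgs_scan",
    "lrt",
    "gwis",
    "discovery",
]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations; an empty list means the config is valid."""
    v: list[str] = []
    if not (0.0 < config.alpha < 1.0):
        v.append(f"alpha must be in (0, 1): {config.alpha}")
    if not (0.0 < config.p_threshold <= 1.0):
        v.append(f"p_threshold must be in (0, 1]: {config.p_threshold}")
    if not (0.0 < config.gwis_p_threshold <= 1.0):
        v.append(f"gwis_p_threshold must be in (0, 1]: {config.gwis_p_threshold}")
    if config.upstream_bp < 0 or config.downstream_bp < 0:
        v.append("variant-to-gene windows must be non-negative")
    if config.locus_window_kb <= 0:
        v.append(f"locus_window_kb must be positive: {config.locus_window_kb}")
    if config.tss_window_kb <= 0:
        v.append(f"tss_window_kb must be positive: {config.tss_window_kb}")
    if not config.outcomes:
        v.append("at least one outcome column is required")
    if not config.exposure:
        v.append("an exposure column name is required")
    if config.min_pathway_variants < 1:
        v.append("min_pathway_variants must be >= 1")
    if config.effective_n_method not in ("participation_ratio", "li_ji"):
        v.append(f"unknown effective_n_method: {config.effective_n_method}")
    try:
        config.simulation.__post_init__()
    except ConfigError as e:
        v.append(str(e))
    return v


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def run_pipeline(config: PipelineConfig, out_dir: Optional[str | Path] = None) -> dict:
    """Execute every stage in dependency order; returns the manifest dict.

    All stage outputs (TSV/JSON) land under ``out_dir``. Any stage error
    aborts with the stage name; partial outputs persist for inspection.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid pipeline config: " + "; ".join(violations))

    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "thresholds": {
            "p_threshold": config.p_threshold,
            "alpha": config.alpha,
            "gwis_p_threshold": config.gwis_p_threshold,
            "upstream_bp": config.upstream_bp,
            "downstream_bp": config.downstream_bp,
            "locus_window_kb": config.locus_window_kb,
            "tss_window_kb": config.tss_window_kb,
            "clump_r2": config.clump.r2_threshold,
            "clump_window_kb": config.clump.window_kb,
        },
        "stages": [],
    }
    save_config(config, out / "config.yaml")

    def record(stage: str, t0: float, **counts) -> None:
        entry = {"stage": stage, "wall_s": round(time.time() - t0, 3), **counts}
        manifest["stages"].append(entry)
        logger.info("stage %s done: %s", stage, counts)

    current = "simulate"
    try:
        t0 = time.time()
        sim = config.simulation
        genes, pathways, variants = generate_annotation(sim)
        genotypes = simulate_genotypes(sim, variants)
        pheno, truth = simulate_phenotypes(
            sim, genotypes, pathways, map_variants_to_genes(variants, genes, config.upstream_bp, config.downstream_bp)
        )
        write_simulation(out / "sim", sim, genes, pathways, variants, genotypes, pheno, truth)
        record("simulate", t0, n_samples=len(pheno), n_variants=len(variants), n_genes=len(genes), n_pathways=len(pathways))

        current = "annotate"
        t0 = time.time()
        vg_map = map_variants_to_genes(variants, genes, config.upstream_bp, config.downstream_bp)
        pv_sets = build_pathway_variant_sets(vg_map, pathways)
        with open(out / "pathway_variant_counts.json", "w") as fh:
            json.dump(pv_sets.counts(), fh, indent=1)
        record("annotate", t0, n_mapped_variants=sum(1 for v in vg_map.mapping.values() if v))

        covariates = config.covariates
        loci_by_outcome, overlap_by_outcome, effn_by_outcome = {}, {}, {}
        for outcome in config.outcomes:
            if outcome not in pheno.columns:
                raise ConfigError(f"outcome column {outcome!r} missing from phenotype table")
            if config.exposure not in pheno.columns:
                raise ConfigError(f"exposure column {config.exposure!r} missing from phenotype table")
            odir = out / outcome
            odir.mkdir(exist_ok=True)

            current = "gwas"
            t0 = time.time()
            ss_main = gwas_main(genotypes, pheno, covariates, outcome_col=outcome)
            write_summary_stats(ss_main, odir / "gwas.tsv")
            record("gwas", t0, n_variants=len(ss_main))

            current = "pgs"
            t0 = time.time()
            gw_weights = build_gwpgs(ss_main, genotypes, config.clump, config.p_threshold)
            ppgs_weights, excluded = build_ppgs(
                gw_weights, pv_sets, ss_main, min_variants=config.min_pathway_variants
            )
            weights_to_frame([gw_weights] + ppgs_weights).to_csv(odir / "weights.tsv", sep="\t", index=False)
            record("pgs", t0, n_gw_variants=gw_weights.n_variants, n_pathway_scores=len(ppgs_weights), n_excluded=len(excluded))

            current = "scores"
            t0 = time.time()
            gw_score = compute_score(genotypes, gw_weights)
            ppgs_scores = [compute_score(genotypes, w) for w in ppgs_weights]
            record("scores", t0, n_scores=1 + len(ppgs_scores))

            current = "gwpgs_test"
            t0 = time.time()
            gw_result = pgs_by_e_test(gw_score, pheno, covariates, config.exposure, outcome)
            record("gwpgs_test", t0, beta_int=round(gw_result.beta_int, 6))

            current = "ppgs_scan"
            t0 = time.time()
            scan_results, bonferroni = run_ppgs_scan(
                ppgs_scores, pheno, covariates, config.exposure, outcome, alpha=config.alpha
            )
            scan_df = interaction_results_frame([gw_result] + scan_results)
            scan_df.loc[0, "significant"] = gw_result.p < config.alpha
            scan_df.to_csv(odir / "interactions.tsv", sep="\t", index=False)
            significant = [r for r in scan_results if r.significant]
            record("ppgs_scan", t0, n_tested=len(scan_results), bonferroni=bonferroni, n_significant=len(significant))

            current = "lrt"
            t0 = time.time()
            lrt = joint_lrt(ppgs_scores, gw_score, pheno, covariates, config.exposure, outcome)
            with open(odir / "lrt.json", "w") as fh:
                json.dump(
                    {
                        "statistic": lrt.statistic,
                        "df": lrt.df,
                        "p": lrt.p,
                        "loglik_full": lrt.loglik_full,
                        "loglik_reduced": lrt.loglik_reduced,
                        "dropped_terms": lrt.dropped_terms,
                    },
                    fh,
                    indent=1,
                )
            record("lrt", t0, statistic=round(lrt.statistic, 3), df=lrt.df)

            current = "gwis"
            t0 = time.time()
            ss_int = gwis_interaction(genotypes, pheno, covariates, config.exposure, outcome)
            write_summary_stats(ss_int, odir / "gwis.tsv")
            record("gwis", t0, n_variants=len(ss_int))

            current = "discovery"
            t0 = time.time()
            loci = prune_loci(ss_int, config.gwis_p_threshold, config.locus_window_kb)
            loci.leads.to_csv(odir / "loci.tsv", sep="\t", index=False)
            sig_ids = [r.scope for r in significant]
            overlap = annotate_explained(
                loci, pathways.subset(sig_ids), genes, config.tss_window_kb
            )
            overlap.per_pathway.to_csv(odir / "overlap.tsv", sep="\t", index=False)
            if sig_ids:
                sig_matrix = np.column_stack(
                    [s.standardized for s in ppgs_scores if s.scope in set(sig_ids)]
                )
                eff_n = effective_n_pathways(sig_matrix, method=config.effective_n_method)
            else:
                eff_n = 0.0
            loci_by_outcome[outcome] = loci
            overlap_by_outcome[outcome] = overlap
            effn_by_outcome[outcome] = eff_n
            record("discovery", t0, n_loci=loci.n_loci, n_significant=len(sig_ids), effective_n=round(eff_n, 2))

        current = "report"
        report = summarize_discovery(
            loci_by_outcome, overlap_by_outcome, effn_by_outcome, config.effective_n_method
        )
        report.table.to_csv(out / "report.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=1, default=float)
    except Exception as e:
        manifest["failed_stage"] = current
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
        raise RuntimeError(f"pipeline stage {current!r} failed: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest
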