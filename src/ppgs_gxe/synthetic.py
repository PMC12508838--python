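"""Synthetic cohort generator: annotations, LD-blocked genotypes, phenotypes.

The generator produces the statistical structure the downstream analysis
assumes, at desk scale:

* non-overlapping gene models on a configurable number of chromosomes, a
  variant table, and random gene sets (pathways);
* additive dosages built from two haplotypes, each thresholded from a latent
  Gaussian AR(1) process so adjacent variants within an LD block are
  correlated (Gaussian-copula LD; no reference panel needed) and variants in
  different blocks or chromosomes are independent;
* a heritable standardized exposure (BMI analogue), biobank-style covariates (age, sex, genomic PCs), and
  a standardized log-scale biomarker outcome with per-variant main effects
  everywhere and interaction effects confined to designated causal pathways.

Within a causal pathway, main and interaction effects can be coupled
(``alpha_beta_corr``); at 1.0 the exposure simply amplifies the pathway's
genetic effects, the architecture under which pathway-restricted scores are
expected to outperform genome-wide ones for interaction detection.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.SeedSequence`` spawn keys (one per stage), so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import PathwayCollection, VariantGeneMap
from .config import ConfigError, SimulationConfig
from .containers import GenotypeMatrix

# SeedSequence spawn keys, one stream per stage
_STREAM_ANNOTATION = 0
_STREAM_GENOTYPES = 1
_STREAM_PHENOTYPES = 2
_STREAM_MISSING = 3


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(stream,))))


def standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale to mean 0, SD 1 (population SD)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def generate_annotation(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, PathwayCollection, pd.DataFrame]:
    """Generate gene models, pathways, and a variant table.

    Genes are placed sequentially (non-overlapping) along each chromosome with
    random lengths and gaps; variant positions are uniform over each
    chromosome, so variants fall inside, near, and between genes. Pathway
    gene sets are sampled without replacement with sizes drawn from
    ``pathway_size_range``.
    """
    if config.n_pathways > 0 and (config.n_genes == 0 or config.n_variants == 0):
        raise ConfigError("cannot generate pathways without genes and variants")
    rng = _rng(config, _STREAM_ANNOTATION)

    chroms = [str(c + 1) for c in range(config.n_chrom)]
    genes_per_chrom = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    genes_per_chrom[: config.n_genes % config.n_chrom] += 1

    rows = []
    chrom_length: dict[str, int] = {}
    gene_counter = 0
    for chrom, n_g in zip(chroms, genes_per_chrom):
        pos = 1
        for _ in range(n_g):
            gap = int(rng.integers(2_000, 20_000))
            length = int(rng.integers(5_000, 50_000))
            start = pos + gap
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (start, end) if strand == "+" else (end, start)
            rows.append(
                {
                    "gene_id": f"GENE{gene_counter:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "tes": tes,
                }
            )
            gene_counter += 1
            pos = end
        chrom_length[chrom] = pos + 10_000
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])

    variants_per_chrom = np.full(config.n_chrom, config.n_variants // config.n_chrom)
    variants_per_chrom[: config.n_variants % config.n_chrom] += 1
    vrows = []
    for chrom, n_v in zip(chroms, variants_per_chrom):
        positions = np.sort(rng.choice(np.arange(1, chrom_length.get(chrom, 100_000)), size=n_v, replace=False))
        for pos in positions:
            vrows.append({"chrom": chrom, "pos": int(pos)})
    variants = pd.DataFrame(vrows)
    variants["variant_id"] = [f"rs{i:06d}" for i in range(len(variants))]
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=len(variants))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(variants))) % 4
    variants["ref"] = bases[ref_idx]
    variants["alt"] = bases[alt_idx]
    lo, hi = config.maf_range
    variants["maf"] = rng.uniform(lo, hi, size=len(variants))
    variants = variants[["variant_id", "chrom", "pos", "ref", "alt", "maf"]]

    pathways = PathwayCollection()
    if config.n_pathways > 0:
        gene_ids = genes["gene_id"].to_numpy()
        size_lo, size_hi = config.pathway_size_range
        for k in range(config.n_pathways):
            size = int(rng.integers(size_lo, size_hi + 1))
            members = rng.choice(gene_ids, size=size, replace=False)
            pathways.add(f"PW{k:03d}", "synthetic pathway", members.tolist())

    unknown = set(config.causal_pathways) - set(pathways.genes)
    if unknown:
        raise ConfigError(f"causal_pathways not among generated pathways: {sorted(unknown)}")
    return genes, pathways, variants


def simulate_genotypes(config: SimulationConfig, variants: pd.DataFrame) -> GenotypeMatrix:
    """Draw dosages as the sum of two copula-thresholded haplotypes.

    Within each LD block of ``ld_block_size`` consecutive variants on a
    chromosome, the latent haplotype Gaussians follow an AR(1) with lag-1
    correlation ``ld_rho``; blocks, and chromosomes, are independent. Each
    latent value is thresholded at the normal quantile of the variant's MAF,
    so the marginal allele frequency is exact by construction.
    """
    if not (0.0 <= config.ld_rho < 1.0):
        raise ConfigError(f"ld_rho must be in [0, 1): {config.ld_rho}")
    rng = _rng(config, _STREAM_GENOTYPES)
    n = config.n_samples
    m = len(variants)
    n_hap = 2 * n

    # variant-major layout keeps the AR(1) recursion on contiguous rows
    latent = rng.standard_normal((m, n_hap))
    rho = config.ld_rho
    scale = np.sqrt(1.0 - rho**2)
    chrom_codes = variants["chrom"].to_numpy()
    chrom_offset = 0
    for j in range(m):
        new_chrom = j == 0 or chrom_codes[j] != chrom_codes[j - 1]
        if new_chrom:
            chrom_offset = j
        # block boundaries (and chromosome starts) restart the AR(1) chain
        block_pos = j - chrom_offset
        if not (new_chrom or block_pos % config.ld_block_size == 0 or rho == 0.0):
            latent[j] *= scale
            latent[j] += rho * latent[j - 1]

    thresholds = stats.norm.ppf(variants["maf"].to_numpy())
    alleles = (latent < thresholds[:, None]).astype(np.int8)
    dosages = (alleles[:, :n] + alleles[:, n:]).T.astype(float)

    if config.missing_rate > 0:
        miss_rng = _rng(config, _STREAM_MISSING)
        mask = miss_rng.random((n, m)) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan

    samples = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants.copy(), samples=samples)


def _draw_effects(
    config: SimulationConfig, rng: np.random.Generator, m: int, causal_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant main effects beta and interaction effects alpha."""
    beta = rng.normal(0.0, config.beta_main_sd, size=m) if config.beta_main_sd > 0 else np.zeros(m)
    alpha = np.zeros(m)
    if causal_cols.size:
        b_sd = config.causal_beta_sd
        if b_sd > 0:
            beta[causal_cols] = rng.normal(0.0, b_sd, size=causal_cols.size)
        a_sd = config.alpha_interaction_sd
        if a_sd > 0:
            c = config.alpha_beta_corr
            noise = rng.normal(0.0, 1.0, size=causal_cols.size)
            if c > 0 and b_sd > 0:
                alpha[causal_cols] = a_sd * (c * beta[causal_cols] / b_sd + np.sqrt(1 - c**2) * noise)
            else:
                alpha[causal_cols] = a_sd * noise
    return beta, alpha


def simulate_phenotypes(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    pathways: PathwayCollection,
    variant_gene_map: VariantGeneMap,
) -> tuple[pd.DataFrame, dict]:
    """Generate covariates, exposure, and the standardized log-scale outcome.

    The exposure is ``sqrt(h2)·(polygenic component) + sqrt(1−h2)·noise``,
    standardized. The outcome is

        y = Σ_j β_j g_j + γ·E + Σ_{j causal} α_j g_j·E + covariate effects + ε,

    then standardized; interaction effects α_j are exactly zero outside
    variants mapped to causal-pathway genes. When
    ``interaction_target_std`` is set, α is rescaled so the standardized
    coefficient of (standardized causal score)×E on the standardized outcome
    equals the target exactly (parameter-recovery experiments need a known
    injected value). Returns the phenotype table and a truth record holding
    β, α, the exposure's polygenic weights, the standardized causal
    interaction score, and any degeneracy warnings.
    """
    rng = _rng(config, _STREAM_PHENOTYPES)
    n, m = genotypes.n_samples, genotypes.n_variants
    variant_ids = genotypes.variants["variant_id"].to_numpy()

    truth_warnings: list[str] = []
    causal_variant_ids: set[str] = set()
    for pid in config.causal_pathways:
        if pid not in pathways:
            raise ConfigError(f"causal pathway {pid} not in the pathway collection")
        member_variants = {
            vid for vid, gset in variant_gene_map.mapping.items() if gset & pathways[pid]
        }
        if not member_variants:
            msg = f"causal pathway {pid} has zero mapped variants; interaction architecture degenerate"
            truth_warnings.append(msg)
            warnings.warn(msg)
        causal_variant_ids |= member_variants
    id_to_col = {v: i for i, v in enumerate(variant_ids)}
    causal_cols = np.array(sorted(id_to_col[v] for v in causal_variant_ids if v in id_to_col), dtype=int)

    G = genotypes.imputed()
    Gc = G - G.mean(axis=0, keepdims=True)

    # covariates
    age = rng.uniform(40.0, 70.0, size=n)
    sex = (rng.random(n) < 0.5).astype(float)
    gpcs = rng.standard_normal((n, config.n_gpcs))

    # heritable exposure
    exposure_weights = rng.standard_normal(m)
    poly = Gc @ exposure_weights
    if config.exposure_h2 > 0:
        poly_std = standardize(poly)
        raw_exposure = np.sqrt(config.exposure_h2) * poly_std + np.sqrt(1 - config.exposure_h2) * rng.standard_normal(n)
    else:
        raw_exposure = rng.standard_normal(n)
    exposure = standardize(raw_exposure)

    beta, alpha = _draw_effects(config, rng, m, causal_cols)
    noise = config.noise_sd * rng.standard_normal(n)
    age_z = standardize(age)

    base = (
        Gc @ beta
        + config.gamma_exposure * exposure
        + config.age_effect * age_z
        + config.sex_effect * (sex - sex.mean())
        + noise
    )

    interaction_coef_std: Optional[float] = None
    causal_score_std: Optional[np.ndarray] = None
    if causal_cols.size and np.any(alpha != 0):
        s_raw = Gc[:, causal_cols] @ alpha[causal_cols]
        s_std = standardize(s_raw)
        se_term = s_std * exposure
        if config.interaction_target_std is not None:
            # choose lam so that lam / SD(base + lam*se_term) == target
            t = config.interaction_target_std
            v_se = se_term.var()
            c_bs = np.cov(base - base.mean(), se_term)[0, 1]
            a = 1.0 - t**2 * v_se
            b = -2.0 * t**2 * c_bs
            c0 = -(t**2) * base.var()
            lam = (-b + np.sqrt(b**2 - 4 * a * c0)) / (2 * a)
            alpha = alpha * (lam / s_raw.std())
            y_raw = base + lam * se_term
            interaction_coef_std = t
        else:
            y_raw = base + s_raw * exposure
            interaction_coef_std = float(s_raw.std() / y_raw.std())
        causal_score_std = s_std
    else:
        y_raw = base
    outcome = standardize(y_raw)

    pheno = pd.DataFrame({"sample_id": genotypes.samples, "outcome": outcome, "exposure": exposure})
    pheno["age"] = age
    pheno["sex"] = sex
    for k in range(config.n_gpcs):
        pheno[f"gpc_{k + 1}"] = gpcs[:, k]

    truth = {
        "beta": dict(zip(variant_ids, beta)),
        "alpha": dict(zip(variant_ids, alpha)),
        "exposure_weights": dict(zip(variant_ids, exposure_weights)),
        "causal_pathways": list(config.causal_pathways),
        "causal_variants": sorted(causal_variant_ids),
        "interaction_coef_std": interaction_coef_std,
        "causal_score_std": causal_score_std,
        "warnings": truth_warnings,
    }
    return pheno, truth


# ---------------------------------------------------------------------------
# writers


def write_variant_table(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages.T, columns=genotypes.samples)
    df.insert(0, "variant_id", genotypes.variant_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a plain-text VCF with GT and DS FORMAT fields.

    Coordinates are 1-based; missing dosages become ``./.:.``.
    """
    var = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        for chrom in pd.unique(var["chrom"]):
            length = int(var.loc[var["chrom"] == chrom, "pos"].max()) + 10_000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(genotypes.n_variants):
            row = var.iloc[j]
            ds = genotypes.dosages[:, j]
            cells = []
            for d in ds:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    gt = gt_codes.get(int(round(d)), "./.")
                    cells.append(f"{gt}:{d:g}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def write_truth(truth: dict, path: str | Path) -> None:
    record = dict(truth)
    if record.get("causal_score_std") is not None:
        record["causal_score_std"] = np.asarray(record["causal_score_std"]).tolist()
    for key in ("beta", "alpha", "exposure_weights"):
        record[key] = {k: float(v) for k, v in record[key].items()}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)


def write_simulation(
    out_dir: str | Path,
    config: SimulationConfig,
    genes: pd.DataFrame,
    pathways: PathwayCollection,
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    truth: dict,
) -> dict[str, str]:
    """Write all simulation artifacts to a directory; returns the file map."""
    from .annotation import write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "pathways": out / "pathways.gmt",
        "variants": out / "variants.tsv",
        "dosages": out / "dosages.tsv",
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
        "config": out / "sim_config.json",
    }
    write_gene_models(genes, paths["genes"])
    write_gmt(pathways, paths["pathways"])
    write_variant_table(variants, paths["variants"])
    write_dosage_tsv(genotypes, paths["dosages"])
    write_vcf(genotypes, paths["vcf"])
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    write_truth(truth, paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(config.to_dict(), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
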