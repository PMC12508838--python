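"""Configuration dataclasses shared across the pipeline.

All thresholds default to the values used throughout the analysis: P&T
p-value threshold 0.001, genome-wide interaction significance 5e-8,
variant-to-gene windows of 2 kb upstream / 1 kb downstream of the gene body,
±500 kb locus pruning, 100 kb TSS window for overlap annotation, and a
family-wise alpha of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The generator emulates the statistical structure the analysis assumes:
    LD-blocked genotypes, a partially heritable continuous exposure (a BMI
    analogue), and a standardized log-scale biomarker outcome whose
    interaction architecture is concentrated in designated causal pathways.

    Effect-size fields are on the outcome's pre-standardization scale:
    ``beta_main_sd`` is the SD of per-allele main effects for variants outside
    causal pathways, ``beta_main_sd_causal`` the (typically larger) SD inside
    causal pathways, and ``alpha_interaction_sd`` the SD of per-allele
    interaction effects (per SD of exposure) for causal-pathway variants.
    ``alpha_beta_corr`` sets the correlation between a variant's main and
    interaction effect within causal pathways; 1.0 is the pure amplification
    architecture in which the exposure scales the pathway's genetic effects.
    """

    n_samples: int = 5000
    n_chrom: int = 2
    n_genes: int = 100
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (5, 10)
    causal_pathways: tuple[str, ...] = ()
    beta_main_sd: float = 0.0
    beta_main_sd_causal: Optional[float] = None
    alpha_interaction_sd: float = 0.0
    alpha_beta_corr: float = 1.0
    interaction_target_std: Optional[float] = None
    gamma_exposure: float = 0.1
    exposure_h2: float = 0.0
    noise_sd: float = 1.0
    n_gpcs: int = 10
    age_effect: float = 0.05
    sex_effect: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5] and be ordered: {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"ld_rho must be in [0, 1): {self.ld_rho}")
        if not (0.0 <= self.exposure_h2 < 1.0):
            raise ConfigError(f"exposure_h2 must be in [0, 1): {self.exposure_h2}")
        if not (0.0 <= self.alpha_beta_corr <= 1.0):
            raise ConfigError(f"alpha_beta_corr must be in [0, 1]: {self.alpha_beta_corr}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate must be in [0, 1): {self.missing_rate}")
        if self.n_pathways > 0 and (self.n_genes == 0 or self.n_variants == 0):
            raise ConfigError("n_pathways > 0 requires n_genes > 0 and n_variants > 0")
        if self.pathway_size_range[0] > self.pathway_size_range[1]:
            raise ConfigError(f"pathway_size_range must be ordered: {self.pathway_size_range}")
        if self.n_pathways > 0 and self.pathway_size_range[1] > self.n_genes:
            raise ConfigError("pathway_size_range exceeds the number of genes")

    @property
    def causal_beta_sd(self) -> float:
        return self.beta_main_sd if self.beta_main_sd_causal is None else self.beta_main_sd_causal

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["pathway_size_range"] = list(self.pathway_size_range)
        d["causal_pathways"] = list(self.causal_pathways)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("maf_range", "pathway_size_range", "causal_pathways"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CovariateSpec:
    """Covariate expansion used by every regression in the pipeline.

    The full adjustment set is age, age², sex, age×sex, K genomic principal
    components and, in interaction models, K exposure×gPC product terms
    (guarding against ancestry-confounded interaction signal).
    """

    age: bool = True
    age_squared: bool = True
    sex: bool = True
    age_by_sex: bool = True
    n_gpcs: int = 10
    exposure_by_gpcs: bool = True

    def columns(self, with_exposure_terms: bool) -> list[str]:
        cols: list[str] = []
        if self.age:
            cols.append("age")
        if self.age_squared:
            cols.append("age_sq")
        if self.sex:
            cols.append("sex")
        if self.age_by_sex:
            cols.append("age_by_sex")
        cols.extend(f"gpc_{k + 1}" for k in range(self.n_gpcs))
        if with_exposure_terms and self.exposure_by_gpcs:
            cols.extend(f"exposure_by_gpc_{k + 1}" for k in range(self.n_gpcs))
        return cols


@dataclass
class ClumpConfig:
    """Greedy LD-clumping parameters (PRSice/PRSet-style defaults)."""

    r2_threshold: float = 0.1
    window_kb: float = 250.0
    p_index_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ConfigError(f"r2_threshold must be in (0, 1]: {self.r2_threshold}")
        if self.window_kb <= 0:
            raise ConfigError(f"window_kb must be positive: {self.window_kb}")


@dataclass
class PipelineConfig:
    """End-to-end run configuration; every threshold is audit-logged."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outcomes: Sequence[str] = ("outcome",)
    exposure: str = "exposure"
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    p_threshold: float = 0.001
    alpha: float = 0.05
    gwis_p_threshold: float = 5e-8
    upstream_bp: int = 2000
    downstream_bp: int = 1000
    locus_window_kb: float = 500.0
    tss_window_kb: float = 100.0
    min_pathway_variants: int = 2
    effective_n_method: str = "participation_ratio"
    seed: int = 0
    out_dir: str = "pipeline_run"

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "outcomes": list(self.outcomes),
            "exposure": self.exposure,
            "covariates": asdict(self.covariates),
            "clump": asdict(self.clump),
            "p_threshold": self.p_threshold,
            "alpha": self.alpha,
            "gwis_p_threshold": self.gwis_p_threshold,
            "upstream_bp": self.upstream_bp,
            "downstream_bp": self.downstream_bp,
            "locus_window_kb": self.locus_window_kb,
            "tss_window_kb": self.tss_window_kb,
            "min_pathway_variants": self.min_pathway_variants,
            "effective_n_method": self.effective_n_method,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "covariates" in d:
            d["covariates"] = CovariateSpec(**d["covariates"])
        if "clump" in d:
            d["clump"] = ClumpConfig(**d["clump"])
        return cls(**d)
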