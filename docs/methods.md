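# Methods

## Generative model (synthetic cohort)

The generator produces the minimal statistical structure the analysis
assumes; it is a study design, not a human-genetics emulator.

**Genotypes.** Each variant j has a target MAF drawn uniformly from
`maf_range` (default 0.05–0.5). A haplotype's allele at variant j is
`1{Z_j < Φ⁻¹(maf_j)}` where Z follows a latent Gaussian AR(1) with lag-1
correlation `ld_rho` (default 0.5) inside blocks of `ld_block_size`
consecutive variants (default 10); blocks and chromosomes are independent.
Dosage = sum of two independent haplotypes, so marginal frequencies are
exact by construction and LD decays geometrically within a block — enough
structure for clumping to be a real operation. Missing dosages can be
injected at `missing_rate` (default 0) to exercise mean imputation.

**Annotations.** Genes are laid end-to-end with random lengths (5–50 kb) and
gaps (2–20 kb) per chromosome, so they never overlap; strands are random, and
`tss`/`tes` are strand-aware (tss > tes on the minus strand). Variant
positions are uniform over each chromosome, so variants fall inside genes,
in flanks, and in intergenic gaps. Pathways are gene sets sampled without
replacement with sizes uniform in `pathway_size_range`; pathways may share
genes, which induces correlated pathway scores downstream (intentional — the
effective-count machinery needs it).

**Exposure.** E* = √h²·P + √(1−h²)·ε with P the standardized genotype score
under random weights and `exposure_h2` default 0 (set to 0.3 for the
exposure-PGS sensitivity analysis); E is E* standardized.

**Outcome.**

    y* = Σⱼ βⱼ gⱼ + γ·E + Σ_{j ∈ causal} αⱼ gⱼ·E + c_age·age_z + c_sex·sex_c + ε,
    y  = standardized y*

βⱼ ~ N(0, `beta_main_sd`²) genome-wide, with a larger scale
`beta_main_sd_causal` for variants mapped to causal-pathway genes
(pathway-concentrated main effects). Interaction effects exist only for
causal-pathway variants: αⱼ = (α_sd/β_sd_causal)·βⱼ by default
(`alpha_beta_corr = 1`), i.e. the exposure *amplifies* the causal pathway's
genetic effects. Marginally αⱼ is still N(0, α_sd²); the proportionality is
the point — pathway scores weight variants by estimated main effects, so a
pathway-restricted score can only detect interactions to the extent main and
interaction effects are correlated within the pathway. With `alpha_beta_corr`
= 0 the score-based tests lose essentially all power by construction, which
is itself the known failure mode of PGS×E testing. The outcome is generated
directly on the standardized log-biomarker scale (the log transform of raw
biomarkers is outside the generator).

When `interaction_target_std` is set, α is rescaled so the coefficient of
(standardized causal score)×E on the standardized outcome equals the target
exactly — parameter-recovery experiments need a known injected value; the
solved quadratic accounts for the variance the interaction term itself adds.

**Covariates.** age ~ U(40, 70), sex ~ Bernoulli(0.5), gPCs i.i.d. N(0,1);
small fixed age/sex effects (0.05 SD) make the adjustment non-vacuous. The
covariates exist to exercise the model structure, not to be demographically
realistic; in particular the gPCs carry no ancestry confounding, so the
E×gPC adjustment is a no-op here (it is kept because the real analysis needs
it and the code path must be exercised).

**Randomness.** All streams derive from one seed via named
`SeedSequence(seed, spawn_key=(stage,))` spawns (annotation / genotypes /
phenotypes / missingness), so each stage is independently reproducible.

## Estimators

**OLS engine.** All regressions are Gaussian OLS solved by QR. p-values use
the t distribution with residual df (indistinguishable from normal at the n
used, but correct at small synthetic n). Robust covariance flavors HC0/HC1/
HC3; HC3 is the default for the GWIS (conservative at moderate n), while
PGS-level tests use model-based SEs by default — robust errors are needed
per-variant, where a single dosage×E regressor interacts with
heteroskedasticity, and are available everywhere via a flag. Rank-deficient
designs raise an error naming the collinear columns (pivoted QR).

**GWAS scan.** Outcome and dosages are residualized on the covariates once
(Frisch–Waugh–Lovell); per-variant estimates equal full refits exactly, and
a unit test enforces agreement to 1e-8. Missing dosages are mean-imputed per
variant; monomorphic variants are emitted flagged with p = 1, never dropped.

**GWIS scan.** Full per-variant refits (the sandwich does not commute with
projection), looped with precomputed covariate blocks.

**Clumping.** Greedy: smallest p first (ties: position, then id), removing
within-window variants with dosage r² ≥ threshold against the retained
index. Defaults r² = 0.1, 250 kb, matching PRSice/PRSet defaults since the
construction follows that program family; in-sample genotypes are the LD
reference. Pairwise correlations come from one gram matrix when the panel is
≤ 4000 variants (per-index products otherwise). Pathway scores restrict the
genome-wide surviving set (clump-then-subset, PRSet's documented behavior);
pathways with fewer than 2 surviving variants are excluded from testing and
do not count toward the Bonferroni denominator.

**Scores.** Additive, mean-imputed dosages, standardized in sample.
Same-sample training and testing is deliberate: for interaction (not main
effect) tests this induces no bias, which the null-calibration experiment
verifies directly (rejection 3–7% at α = 0.05).

**Joint LRT.** Reduced: covariates + E + gwPGS + gwPGS·E + all pathway-score
main effects; full adds all pathway-score·E terms, so the test isolates
interaction signal. Gaussian ML (not REML) log-likelihoods; χ² with df =
retained interaction terms. Aliased score columns are dropped by pivoted QR
and reported; a variant with mains only in the full model is available
(`mains_in_reduced=False`). The placement of pathway mains in both models is
a design choice; with mains in the full model only, the test confounds main
and interaction pathway signal.

**Locus pruning and overlap.** Lead = smallest p among remaining significant
variants; removal within ±500 kb. A significant pathway is *explained* iff a
lead lies within 100 kb (inclusive) of the strand-aware TSS of a member
gene. Unexplained fractions are reported as integer percents, rounding
half away from zero.

**Effective pathway count.** Participation ratio (Σλ)²/Σλ² over the
eigenvalues of the Pearson correlation matrix of the significant pathway
scores — bounded by [1, K], equal to K for uncorrelated scores and 1 for
identical ones. This is this package's chosen operationalization of a
PCA-based effective count (a Li–Ji-style count is available as
`method="li_ji"`); the method name is recorded in the report metadata.

## Study conditions for the replicated experiments

Fixed in `ppgs_gxe.experiments`; replicate seeds are enumerated ranges.

| experiment | n | variants | pathways | effects |
|---|---|---|---|---|
| null calibration | 5000 | 500 | 20 | β_sd 0.1, α = 0 |
| recovery | 10000 | 500 | 20 | injected standardized interaction pinned at 0.05 |
| power ordering | 5000 | 500 | 20 | β_sd 0.1 (causal 0.25), α_sd 0.05, one causal pathway |
| joint-LRT null | 3000 | 300 | 10 | β_sd 0.1, α = 0 |

The power-ordering scales were chosen so that roughly a fifth of null
variants pass the 0.001 threshold (so the genome-wide score is genuinely
diluted), the causal pathway's variants are almost always retained, and the
total standardized pathway interaction (~0.08–0.10) sits well above the
pathway Bonferroni bar while individual variant interaction z-scores stay
far below genome-wide significance — the regime in which pathway-level
testing is the only scale that discovers the signal. Recovery uses the
causal pathway's true weighted score (oracle weights), so the estimate is
unbiased for the injected value and ±2 SE coverage is interpretable as CI
coverage; with estimated weights the same experiment measures attenuation
instead.

## What passing tests do and do not show

The generator's LD is block-geometric with no long-range structure,
frequencies are uniform rather than ascertained, samples are unrelated and
unstructured, and effect architectures are Gaussian with exact pathway
proportionality. Passing tests therefore validate the *machinery* —
estimator correctness, calibration, the power ordering under the
architecture that motivates pathway-level testing — not performance on real
cohort data, where pathway annotations are wrong in places, main/interaction
proportionality is partial, and confounding is real.

## Numerical choices

- Strict inequality at the p threshold (p = 0.001 exactly is excluded); a
  documented arbitrary choice.
- Standardization uses population (ddof = 0) moments; standardized columns
  are checked to mean 0 / SD 1 within 1e-6.
- Monomorphic or degenerate-interaction variants: flagged rows with p = 1.
- Clump/prune tie-breaks (p, then position, then id) make both greedy
  algorithms order-invariant; tests shuffle inputs to enforce this.
- Li–Ji eigenvalues are rounded to 10 decimals before `floor` to avoid
  λ = K − 1e−15 artifacts.
- The LRT statistic is clipped at 0 (floating-point nesting noise).

## Limitations

- No allele flipping/strand reconciliation in scoring: effect alleles must
  match the genotype alt allele (synthetic data guarantees this; real
  summary stats would need harmonization first).
- One continuous exposure per run; quantitative outcomes only; no
  relatedness or mixed models.
- Variant→gene mapping is purely positional; no functional (eQTL/chromatin)
  evidence.
- The effective-count formula is a reasonable bounded choice, not the only
  one; report it with its name.
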