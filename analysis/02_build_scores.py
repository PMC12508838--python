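"""GWAS, P&T clumping/thresholding, genome-wide and pathway score construction.

Reads results/cohort/, writes weights and standardized scores under
results/scores/.
"""

from common import RESULTS, load_cohort

from ppgs_gxe.annotation import build_pathway_variant_sets, map_variants_to_genes
from ppgs_gxe.assoc import gwas_main, write_summary_stats
from ppgs_gxe.config import ClumpConfig, CovariateSpec
from ppgs_gxe.pgs import build_gwpgs, build_ppgs, compute_score, scores_to_frame, weights_to_frame


def main() -> None:
    d = load_cohort()
    out = RESULTS / "scores"
    out.mkdir(parents=True, exist_ok=True)
    covariates = CovariateSpec()

    sumstats = gwas_main(d["genotypes"], d["pheno"], covariates)
    write_summary_stats(sumstats, out / "gwas.tsv")
    print(f"GWAS: {len(sumstats)} variants, {(sumstats['p'] < 0.001).sum()} at p < 0.001")

    gw = build_gwpgs(sumstats, d["genotypes"], ClumpConfig(), p_threshold=0.001)
    vg_map = map_variants_to_genes(d["variants"], d["genes"])
    pv_sets = build_pathway_variant_sets(vg_map, d["pathways"])
    ppgs, excluded = build_ppgs(gw, pv_sets, sumstats)
    print(f"P&T: {gw.n_variants} variants survive clumping (r2 0.1, 250 kb) + threshold 0.001")
    print(f"pathway scores: {len(ppgs)} testable, {len(excluded)} excluded (<2 surviving variants)")

    weights_to_frame([gw] + ppgs).to_csv(out / "weights.tsv", sep="\t", index=False)
    scores = [compute_score(d["genotypes"], w) for w in [gw] + ppgs]
    scores_to_frame(scores).to_csv(out / "scores.tsv", sep="\t", index=False)
    print("wrote weights.tsv and scores.tsv")


if __name__ == "__main__":
    main()
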