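"""PGS×E interaction testing: genome-wide score, pathway scan, joint LRT.

Reads results/cohort/ and results/scores/, writes interaction results and the
LRT report under results/interactions/.
"""

import json

import pandas as pd

from common import RESULTS, load_cohort

from ppgs_gxe.config import CovariateSpec
from ppgs_gxe.containers import ScoreVector
from ppgs_gxe.interaction import interaction_results_frame, joint_lrt, pgs_by_e_test, run_ppgs_scan


def load_scores() -> list[ScoreVector]:
    df = pd.read_csv(RESULTS / "scores" / "scores.tsv", sep="\t")
    out = []
    for scope, grp in df.groupby("scope", sort=False):
        out.append(
            ScoreVector(
                scope=str(scope),
                raw=grp["raw"].to_numpy(),
                standardized=grp["standardized"].to_numpy(),
                n_variants=0,
                samples=grp["sample_id"].tolist(),
            )
        )
    return out


def main() -> None:
    d = load_cohort()
    out = RESULTS / "interactions"
    out.mkdir(parents=True, exist_ok=True)
    covariates = CovariateSpec()

    scores = load_scores()
    gw = next(s for s in scores if s.scope == "genome_wide")
    ppgs = [s for s in scores if s.scope != "genome_wide"]

    gw_res = pgs_by_e_test(gw, d["pheno"], covariates)
    print(f"gwPGS x exposure: beta = {gw_res.beta_int:.4f} (SE {gw_res.se:.4f}), p = {gw_res.p:.3g}")

    scan, bonferroni = run_ppgs_scan(ppgs, d["pheno"], covariates, alpha=0.05)
    table = interaction_results_frame([gw_res] + scan)
    table.to_csv(out / "interactions.tsv", sep="\t", index=False)
    sig = [r for r in scan if r.significant]
    print(f"pathway scan: {len(scan)} tested, Bonferroni threshold {bonferroni:.3g}, "
          f"{len(sig)} significant: {', '.join(r.scope for r in sig)}")
    best = min(scan, key=lambda r: r.p)
    print(f"top pathway {best.scope}: beta = {best.beta_int:.4f}, p = {best.p:.3g} "
          f"(gwPGS p = {gw_res.p:.3g})")

    lrt = joint_lrt(ppgs, gw, d["pheno"], covariates)
    with open(out / "lrt.json", "w") as fh:
        json.dump(
            {"statistic": lrt.statistic, "df": lrt.df, "p": lrt.p, "dropped": lrt.dropped_terms},
            fh, indent=1,
        )
    print(f"joint LRT (all pathway interactions vs genome-wide only): "
          f"chi2 = {lrt.statistic:.1f}, df = {lrt.df}, p = {lrt.p:.3g}")


if __name__ == "__main__":
    main()
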