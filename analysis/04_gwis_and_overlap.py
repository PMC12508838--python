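"""Single-variant GWIS, locus pruning, explained/unexplained overlap, effective-N.

Reads results/cohort/ and results/interactions/, writes the GWIS scan, lead
loci, overlap table and the summary report under results/discovery/.
"""

import json

import numpy as np
import pandas as pd

from common import RESULTS, load_cohort

from ppgs_gxe.assoc import gwis_interaction, write_summary_stats
from ppgs_gxe.config import CovariateSpec
from ppgs_gxe.discovery import annotate_explained, effective_n_pathways, prune_loci, summarize_discovery


def main() -> None:
    d = load_cohort()
    out = RESULTS / "discovery"
    out.mkdir(parents=True, exist_ok=True)

    gwis = gwis_interaction(d["genotypes"], d["pheno"], CovariateSpec())
    write_summary_stats(gwis, out / "gwis.tsv")
    print(f"GWIS: {len(gwis)} variants, min robust p = {gwis['p'].min():.3g}")

    loci = prune_loci(gwis, p_threshold=5e-8, window_kb=500)
    loci.leads.to_csv(out / "loci.tsv", sep="\t", index=False)
    print(f"lead loci at p < 5e-8 after +-500 kb pruning: {loci.n_loci}")

    interactions = pd.read_csv(RESULTS / "interactions" / "interactions.tsv", sep="\t")
    sig = interactions[(interactions["scope"] != "genome_wide") & interactions["significant"]]
    overlap = annotate_explained(loci, d["pathways"].subset(sig["scope"]), d["genes"], tss_window_kb=100)
    overlap.per_pathway.to_csv(out / "overlap.tsv", sep="\t", index=False)
    pct = overlap.percent_unexplained
    print(f"significant pathways: {overlap.n_significant_pathways}, "
          f"unexplained by GWIS loci: {overlap.n_unexplained}"
          + (f" ({pct}%)" if pct is not None else ""))

    if len(sig):
        scores = pd.read_csv(RESULTS / "scores" / "scores.tsv", sep="\t")
        cols = [
            scores.loc[scores["scope"] == s, "standardized"].to_numpy()
            for s in sig["scope"]
        ]
        eff = effective_n_pathways(np.column_stack(cols))
        print(f"effective number of discovered pathways (participation ratio): {eff:.2f}")
    else:
        eff = 0.0

    report = summarize_discovery({"outcome": loci}, {"outcome": overlap}, {"outcome": eff})
    report.table.to_csv(out / "report.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, default=float)
    print("wrote gwis.tsv, loci.tsv, overlap.tsv, report.tsv/json")


if __name__ == "__main__":
    main()
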