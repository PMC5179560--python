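"""Per-miR target-direction enrichment and miR-mRNA network construction.

For each sex: intersect the two prediction sources, restrict targets to the
analysis universe, test every differentially expressed miR's target
direction frequencies against the transcriptome background (chi-squared
goodness of fit, df 2), select survivors by Benjamini-Hochberg at 0.05,
build the signed bipartite network, and summarize its composition.

    python analysis/04_network.py [--outdir results]
"""

import argparse
from pathlib import Path

from sexmir import io_formats
from sexmir.differential_expression import AnalysisThresholds, DEResult
from sexmir.mir_target_network import (
    annotate_mir_log2fc,
    chi_squared_target_enrichment,
    classify_associations,
    intersect_target_sources,
    negative_subnetwork,
    select_surviving,
    summarize_network,
)

CONTRASTS = {"male": "stress_in_males", "female": "stress_in_females"}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    th = AnalysisThresholds()

    de_mrna = DEResult(io_formats.read_table(args.outdir / "de_mrna.tsv"),
                       list(CONTRASTS.values()), th)
    de_mir = DEResult(io_formats.read_table(args.outdir / "de_mir.tsv"),
                      list(CONTRASTS.values()), th)
    predictions = io_formats.read_target_predictions(args.outdir / "inputs" / "targets.tsv")
    universe = set(de_mrna.feature_ids)
    tmap = intersect_target_sources(predictions, predictions.sources, universe=universe)
    print(f"dual-source intersection: {sum(len(t) for t in tmap.values())} "
          f"(miR, target) pairs over {len(tmap)} miRs inside the {len(universe)}-gene universe")

    for sex, contrast in CONTRASTS.items():
        dirs = de_mir.directions(contrast)
        de_dirs = dirs[dirs != "neutral"]
        enrich = chi_squared_target_enrichment(tmap, de_mrna, contrast, de_dirs)
        surviving = select_surviving(enrich, th.network_bh_alpha)
        net = classify_associations(surviving, tmap, de_mrna, contrast)
        annotate_mir_log2fc(net, de_mir, contrast)
        net.validate()
        summary = summarize_network(net, de_mrna, contrast, surviving,
                                    n_de_mirs=len(de_dirs))

        io_formats.write_table([e.as_row() for e in enrich],
                               args.outdir / f"chisq_{sex}.tsv")
        io_formats.write_network(net, args.outdir / f"network_{sex}.tsv", "edge-TSV")
        io_formats.write_network(negative_subnetwork(net),
                                 args.outdir / f"network_{sex}_negative.sif", "SIF")
        io_formats.write_network(net, args.outdir / f"network_{sex}.graphml", "GraphML")
        io_formats.write_table([summary.as_row()],
                               args.outdir / f"network_summary_{sex}.tsv")

        n_neg = sum(1 for _, _, a in net.iter_edges() if a == "negative")
        print(f"{sex}: {len(surviving)}/{len(enrich)} DE miRs survive BH "
              f"({100 * summary.fraction_mirs_surviving:.0f}%); "
              f"{summary.n_genes_targeted} of {summary.n_de_genes} DE genes targeted "
              f"({100 * summary.fraction_genes_targeted:.0f}%); "
              f"{net.n_edges} edges ({n_neg} negative); "
              f"{summary.genes_by_multiple_mirs} genes hit by 2+ miRs")


if __name__ == "__main__":
    main()
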