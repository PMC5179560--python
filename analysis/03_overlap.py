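"""Directional list-overlap analysis, within and between sexes.

Part 1 recomputes the published pairwise overlaps from their printed list
sizes against the fixed candidate backgrounds (19,827 mRNAs; 781 miRs) —
these are pure closed-form hypergeometric tails and need no data.  Part 2
runs the same test on the directional lists produced by
02_differential_expression.py against the simulated analysis universe.

    python analysis/03_overlap.py [--outdir results]
"""

import argparse
from pathlib import Path

from sexmir import io_formats
from sexmir.differential_expression import AnalysisThresholds, DEResult
from sexmir.overlap_analysis import fisher_overlap, pairwise_overlaps

PRINTED = [
    ("mrna male-up(324) x female-up(116), k=9", 324, 116, 9, 19827),
    ("mrna male-down(1025) x female-down(232), k=39", 1025, 232, 39, 19827),
    ("mrna male-up(324) x female-down(232), k=12", 324, 232, 12, 19827),
    ("mrna male-down(1025) x female-up(116), k=9", 1025, 116, 9, 19827),
    ("mir male-up(25) x female-up(18), k=3", 25, 18, 3, 781),
]

CONTRASTS = {"male": "stress_in_males", "female": "stress_in_females"}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    print("published overlaps recomputed from printed set sizes:")
    rows = []
    for label, n_a, n_b, k, N in PRINTED:
        p = fisher_overlap(n_a, n_b, k, N)
        rows.append({"comparison": label, "n_a": n_a, "n_b": n_b, "k": k,
                     "background": N, "p_value": p})
        print(f"  {label}: p = {p:.3g}")
    io_formats.write_table(rows, args.outdir / "overlaps_printed_sizes.tsv")

    sim_rows = []
    for assay in ("mrna", "mir"):
        de = DEResult(
            io_formats.read_table(args.outdir / f"de_{assay}.tsv"),
            list(CONTRASTS.values()),
            AnalysisThresholds(),
        )
        lists = {
            f"{assay}_{sex}_{d}": de.directional_list(c, d)
            for sex, c in CONTRASTS.items()
            for d in ("up", "down")
        }
        background = len(de.table)
        for r in pairwise_overlaps(lists, background):
            sim_rows.append(r.as_row())
    io_formats.write_table(sim_rows, args.outdir / "overlaps_simulated.tsv")
    sig = sum(r["p_value"] < 0.05 for r in sim_rows)
    print(f"simulated data: {len(sim_rows)} pairwise comparisons, {sig} at p < 0.05 "
          f"-> {args.outdir / 'overlaps_simulated.tsv'}")


if __name__ == "__main__":
    main()
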