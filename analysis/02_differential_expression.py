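"""Filter + precision-weighted differential expression for both assays.

Reads the count matrices and design written by 01_simulate.py, applies the
expression filter (> 5 reads in >= 80% of samples of some condition cell),
fits the weighted sex x stress factorial with empirical-Bayes moderated
t-tests, and classifies every feature up/down/neutral per within-sex stress
contrast (uncorrected p < 0.05, fold change >= 1.3).

    python analysis/02_differential_expression.py [--outdir results]
"""

import argparse
from pathlib import Path

from sexmir import io_formats
from sexmir.differential_expression import run_differential_expression


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    inp = args.outdir / "inputs"

    design = io_formats.read_design(inp / "design.csv")
    for assay, fname in (("mRNA", "mrna_counts.tsv"), ("miR", "mir_counts.tsv")):
        counts = io_formats.read_count_matrix(inp / fname, assay)
        de = run_differential_expression(counts, design)
        out = args.outdir / f"de_{assay.lower()}.tsv"
        io_formats.write_table(de.table, out)
        print(f"{assay}: {counts.n_features} features, {len(de.table)} pass the filter")
        for contrast in de.contrasts:
            up = len(de.directional_list(contrast, "up"))
            down = len(de.directional_list(contrast, "down"))
            print(f"  {contrast}: {up} up, {down} down")
        print(f"  -> {out}")


if __name__ == "__main__":
    main()
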