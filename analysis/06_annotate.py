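#!/usr/bin/env python
"""Annotate consensus outliers and significant windows with nearby genes.

Outlier SNPs are linked to genes whose intervals come within 5 kb;
significant windows retrieve only overlapping genes.  Without a --genes
BED/GFF3 file, a synthetic gene set placed on the simulated genome is
used so the join logic can be exercised end to end.
"""

import argparse
from pathlib import Path

import pandas as pd

from thermadapt import pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--run", type=Path, default=Path("results/run"))
parser.add_argument("--genes", type=Path, default=None,
                    help="BED or GFF3 gene intervals")
parser.add_argument("--trait", default="fh20")
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

scan_tab = pd.read_csv(args.run / "outlier_scan.tsv", sep="\t")
cons = scan_tab[scan_tab["consensus"]]
if args.genes:
    genes = pipeline.read_gene_intervals(args.genes)
else:
    genes = pipeline._synthetic_gene_set(args.seed)
    print(f"using a synthetic gene set ({len(genes)} intervals)")

windows_path = args.run / f"windows_{args.trait}.tsv"
windows = None
if windows_path.exists():
    w = pd.read_csv(windows_path, sep="\t")
    windows = w[w["significant"]][["chrom", "start", "end"]]

snp_genes, window_genes = pipeline.proximity_annotate(
    cons[["locus_id", "chrom", "pos_bp"]], genes, windows=windows)
snp_genes.to_csv(args.run / "outlier_gene_annotation.tsv", sep="\t",
                 index=False)
hit = (snp_genes["genes"] != "").sum()
print(f"{hit}/{len(snp_genes)} consensus outliers lie within 5 kb of a gene")
if window_genes is not None:
    window_genes.to_csv(args.run / "window_gene_annotation.tsv", sep="\t",
                        index=False)
    whit = (window_genes["genes"] != "").sum()
    print(f"{whit}/{len(window_genes)} significant windows overlap a gene")
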