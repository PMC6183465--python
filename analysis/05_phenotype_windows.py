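#!/usr/bin/env python
"""Genotype-phenotype window scan within each ecotype.

Fish are ranked per population on a cardiac trait and split evenly into
low/high classes; loci genotyped in at least 75% of the ecotype's fish
are tested per marker (two-group F_ST and a two-sided Fisher exact test
on allele counts) and combined over 10 kb windows stepped every 200 bp
with Stouffer's weighted z.  Window significance is BY-FDR controlled.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from thermadapt import association, cardiac, genotypes

parser = argparse.ArgumentParser()
parser.add_argument("--run", type=Path, default=Path("results/run"))
parser.add_argument("--trait", default="fh20",
                    choices=["fh20", "fh_peak", "t_ab", "t_peak"])
args = parser.parse_args()

g = genotypes.read_genotypes(args.run / "genotypes_filtered.tsv",
                             args.run / "pop_map.tsv")
frame = pd.read_csv(args.run / "cardiac_summaries.tsv", sep="\t")

all_windows = []
for ecotype, eco_frame in frame.groupby("ecotype", sort=False):
    labels = association.split_phenotype_classes(eco_frame, args.trait)
    fish_idx = np.flatnonzero(g.individuals["ecotype"].to_numpy() == ecotype)
    keep = association.class_coverage_filter(g, fish_idx)
    sub = g.subset_individuals(fish_idx).subset_loci(keep)
    markers = association.marker_class_tests(sub, labels)
    markers = markers.sort_values(["chrom", "pos_bp"],
                                  kind="stable").reset_index(drop=True)
    win = association.window_scan(markers)
    win.insert(0, "ecotype", ecotype)
    all_windows.append(win)
    n_sig = int(win["significant"].sum())
    print(f"{ecotype:13s}: {keep.sum()} loci pass coverage, "
          f"{len(win)} windows, {n_sig} significant for {args.trait}")

windows = pd.concat(all_windows, ignore_index=True)
windows.to_csv(args.run / f"windows_{args.trait}.tsv", sep="\t", index=False)
sig = windows[windows["significant"]]
print(f"total significant windows for {args.trait}: {len(sig)}")
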