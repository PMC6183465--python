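#!/usr/bin/env python
"""Apply the four catalog-cleaning rules and summarise heterozygosity.

Rules, in order: (a) tags with more than four SNPs, (b) multi-allelic
SNPs, (c) SNPs missing more than 25% of genotypes, (d) SNPs with minor
allele frequency below 0.02 in any population.
"""

import argparse
from pathlib import Path

from thermadapt import genotypes

parser = argparse.ArgumentParser()
parser.add_argument("--run", type=Path, default=Path("results/run"))
args = parser.parse_args()

g = genotypes.read_genotypes(args.run / "genotypes.tsv",
                             args.run / "pop_map.tsv")
filtered, report = genotypes.filter_catalog(g)
report.to_frame().to_csv(args.run / "filter_report.tsv", sep="\t", index=False)
genotypes.write_tab_matrix(filtered, args.run / "genotypes_filtered.tsv")
print(report)

per_locus, means = genotypes.locus_stats(filtered)
means.round(4).to_csv(args.run / "heterozygosity.tsv", sep="\t", index=False)
print("\nper-population mean heterozygosity:")
print(means.round(3).to_string(index=False))
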