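#!/usr/bin/env python
"""Scan for selection outliers among the six demes and link them to
stream temperature.

Runs the trimmed-F_ST null and the PCA communality scan (and, with
--with-bayes, the Bayesian F_ST decomposition) on the filtered panel,
calls the consensus (loci flagged by at least two methods), checks the
recovery of the planted clinal loci, ranks consensus outliers by the
strength of their minor-allele-frequency ~ temperature regression, and
runs structure PCA plus Mantel isolation-by-distance/temperature tests.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from thermadapt import association, genotypes, scan, simulate

parser = argparse.ArgumentParser()
parser.add_argument("--run", type=Path, default=Path("results/run"))
parser.add_argument("--with-bayes", action="store_true",
                    help="include the MCMC scan (minutes of extra runtime)")
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

g = genotypes.read_genotypes(args.run / "genotypes_filtered.tsv",
                             args.run / "pop_map.tsv")
truth = simulate.SimulationTruth.load(args.run / "truth.tsv")

res = scan.scan_outliers(
    g, run_bayes=args.with_bayes,
    bayes_config=scan.BayesScanConfig(seed=args.seed))
res.table.to_csv(args.run / "outlier_scan.tsv", sep="\t", index=False)

tab = res.table
cons = tab[tab["consensus"]]
print(f"methods flagged: trimmed-null {int(tab['trimmed_null_sig'].sum())}, "
      f"pca {int(tab['pca_sig'].sum())}"
      + (f", bayes {int(tab['bayes_sig'].sum())}" if args.with_bayes else ""))
print(f"consensus outliers (>=2 methods): {len(cons)} of {len(tab)} loci")
print(f"inflation factors: trimmed {res.lambda_trimmed:.3f}, "
      f"pca {res.lambda_pca:.3f}")

causal = set(truth.causal_locus_ids) & set(tab["locus_id"])
called = set(cons["locus_id"])
print(f"planted-cline recovery: {len(called & causal)}/{len(causal)} causal, "
      f"{len(called - causal)} neutral false positives")

# temperature association of the consensus outliers
temps = pd.Series(simulate.DEFAULT_POP_TEMPS, index=list(simulate.DEFAULT_POPS))
maf = association.minor_allele_frequencies(g)
maf_out = maf[maf.index.isin(called)]
if len(maf_out) >= 1:
    top = association.maf_temperature_association(maf_out, temps, top_n=20)
    top.round(5).to_csv(args.run / "temperature_associated_loci.tsv",
                        sep="\t", index=False)
    print(f"top temperature-associated outliers: {len(top)} "
          f"(best r2 {top['r2'].iloc[0]:.2f})")

# population structure on neutral vs outlier loci
neutral_mask = ~tab["consensus"].to_numpy()
coords_n, var_n = association.structure_pca(g, np.flatnonzero(neutral_mask))
coords_o, var_o = association.structure_pca(g, np.flatnonzero(~neutral_mask)) \
    if (~neutral_mask).sum() >= 2 else (None, None)
coords_n.round(3).to_csv(args.run / "pca_neutral.tsv", sep="\t")
if coords_o is not None:
    coords_o.round(3).to_csv(args.run / "pca_outliers.tsv", sep="\t")
print(f"neutral PCA: PC1 explains {var_n[0]:.1%}")

# isolation by temperature: linearised pairwise F_ST vs |dT|
fst_pw = association.pairwise_linearized_fst(g)
dtemps = np.abs(temps.to_numpy()[:, None] - temps.to_numpy()[None, :])
r, p = association.mantel(fst_pw.to_numpy(), dtemps, n_perm=9999,
                          seed=args.seed)
print(f"Mantel isolation-by-temperature (all loci): r={r:.3f} p={p:.4f}")
fst_pw.round(4).to_csv(args.run / "pairwise_fst.tsv", sep="\t")
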