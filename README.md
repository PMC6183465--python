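# thermadapt

Cardiac thermal-performance phenotyping and population-genomic selection
scans for fish populations adapted to divergent thermal regimes.

Ectotherm distributions are bounded by temperature, and in salmonids the
heart is a leading candidate for the limiting organ: as water warms,
oxygen demand rises and maximum heart rate (f_h,max) must keep pace until
it plateaus and fails. Field studies of desert- and montane-stream
redband trout combine two lines of evidence — per-fish cardiac
phenotypes from acute-warming ECG trials, and dense RAD-seq genotypes
scanned for selection — to ask whether populations from extreme climates
have evolved both their cardiac performance and the underlying genomic
regions. This package implements that entire analysis as a reusable,
tested pipeline, together with a synthetic-data generator that plants
known truth so every stage can be validated end to end.

## What it computes

**Cardiac phenotypes** (`thermadapt.cardiac`) from temperature-stepped
maximum-heart-rate trials: mass-corrected f_h,max at 20 °C, peak
f_h,max, the Arrhenius breakpoint temperature T_AB (intersection of two
least-squares lines in ln f_h,max vs 1/K, exhaustive split search), the
peak temperature T_PEAK (first >5 bpm/°C drop or arrhythmia), and
Q10 = (f₂/f₁)^(10/(t₂−t₁)).

**Genotype QC** (`thermadapt.genotypes`): VCF / tab-matrix I/O, the
four-rule RAD catalog filter (tags with >4 SNPs; multi-allelic SNPs;
>25% missingness; minor allele frequency <0.02 in any population), and
unbiased heterozygosity.

**Selection scans** (`thermadapt.scan`): per-locus Weir–Cockerham θ from
variance components; a trimmed-F_ST chi-square null fitted by truncated
maximum likelihood; a PCA communality test (k = 3) with robust
Mahalanobis distances calibrated by the genomic inflation factor; a
Bayesian logistic F_ST decomposition sampled by reversible-jump MCMC
(Bayes factor ≥ 3 at FDR 0.1); Benjamini–Yekutieli FDR; and the
consensus rule that keeps loci flagged by at least two methods.

**Association** (`thermadapt.association`): within-ecotype low/high
phenotype classes; per-marker Fisher exact tests and two-class F_ST;
10 kb / 200 bp sliding-window combination by Stouffer's weighted z with
BY-FDR significance; an optional Lindley local-score segmentation;
minor-allele-frequency ~ summer-temperature regressions; Mantel tests;
structure PCA with mean imputation.

**Orchestration** (`thermadapt.pipeline`, `thermadapt.cli`): a YAML-
configured `run_pipeline` covering simulate → cardiac → qc → scan →
assoc → annotate (gene proximity within 5 kb of outlier SNPs; overlap
only for windows), exposed as the `thermadapt` command with matching
subcommands. The numbered scripts under `analysis/` run the same stages
as a narrative, one step per script.

## Worked example

```
$ python analysis/01_simulate_cohort.py --seed 1 --n-loci 4000 --out results/run
simulated 120 fish x 4000 loci (50 clinal, slope +0.20/degC)
simulated 120 acute-warming trials (2 bpm noise)

$ python analysis/02_cardiac_phenotypes.py --run results/run
120 fish summarised; breakpoint resolved for 96
...
ecotype mean fh20 ordering: desert > cool_montane > cold_montane

$ python analysis/03_filter_genotypes.py --run results/run
$ python analysis/04_selection_scan.py --run results/run
methods flagged: trimmed-null 31, pca 36
consensus outliers (>=2 methods): 30 of 3442 loci
inflation factors: trimmed 1.007, pca 1.029
planted-cline recovery: 30/41 causal, 0 neutral false positives
top temperature-associated outliers: 20 (best r2 0.99)
Mantel isolation-by-temperature (all loci): r=0.907 p=0.0116
```

Reading the numbers: of the 50 planted clinal loci, 41 survive the
catalog filter (strong clines push some deme frequencies under the MAF
rule, as in real data) and 30 are recovered by the two-method consensus
with zero neutral false positives; the 20 outliers most associated with
stream temperature regress on the planted cline almost perfectly; and
pairwise differentiation increases with the temperature difference
between streams (Mantel r = 0.91). Desert fish end up with the highest
heart rates purely because the clinal alleles they carry also raise the
simulated phenotypes — the same inheritance logic the field study
posits. Warming trials lose some breakpoints to noise (96/120), matching
the reduced per-population T_AB sample sizes field studies report.

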