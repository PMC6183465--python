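# Methods

`thermadapt` re-implements, as one tested pipeline, an integrated analysis
of thermal adaptation in stream fish: cardiac thermal-performance
phenotypes derived from acute-warming heart-rate trials, genome scans for
selection outliers across populations, and genotype–phenotype /
genotype–environment association through a sliding-window F_ST procedure.
Because the raw study data (per-fish trials, RAD-seq genotypes) are not
reproducible at desk scale, every claim the package makes is checked on
synthetic cohorts with planted truth. This note records the models, the
parameters that matter, and the design decisions taken where the
procedure left genuine freedom.

## Cardiac phenotypes

A trial is an ordered 1 °C-per-step ladder of test temperatures with the
fish's maximum heart rate (f_h,max, bpm) and an arrhythmia flag per step.
Derived phenotypes:

* **Mass correction.** Rates are corrected to a common 11 g body mass
  with `corrected = fh · (mass/11)^0.1` (allometric exponent −0.1); the
  correction is multiplicative and exactly invertible.
* **Peak detection (T_PEAK).** Scanning in temperature order, the trial
  peak triggers at the first step whose rate falls *strictly more than*
  5 bpm below the previous step, or at the first arrhythmic step.
  T_PEAK is the temperature of the maximum recorded rate at or before
  the trigger; peak f_h,max is the maximum non-arrhythmic rate there.
  Trials that never trigger are labelled `end_of_trial`.
* **Arrhenius breakpoint (T_AB).** On the Arrhenius plot
  (x = 1/(T+273.15), y = ln f_h,max) of the steps up to T_PEAK, every
  split leaving ≥ 3 points per segment is fitted by ordinary least
  squares on each side; the split minimising total RSS wins and T_AB is
  the intersection of the two lines. The search is exhaustive, so a
  brute-force oracle can check it exactly. T_AB is reported *absent*
  (not an error) when fewer than six points are available, when the two
  slopes differ by less than a relative 1e-3 (single-phase curve), or
  when the intersection falls outside the fitted range — mirroring field
  data, where some fish yield no breakpoint.
* **Q10** = (f2/f1)^(10/(t2−t1)) between the 15 °C step and the peak;
  **fh20** is the mass-corrected rate at the ladder step nearest 20 °C
  (within ±0.5 °C; trials step in 1 °C increments, so interpolation is
  not warranted).

## Genotype filters and summary statistics

Genotypes are biallelic codes 0/1/2 (alt-allele count, −1 missing) with
RAD-tag, chromosome and position metadata. The catalog filter applies, in
order: (a) drop all SNPs on tags carrying **more than four** SNPs;
(b) drop multi-allelic SNPs (flagged upstream — the in-memory code space
is already biallelic); (c) drop SNPs missing **more than 25%** of
genotypes across all populations jointly; (d) drop SNPs whose
*per-population* minor allele frequency falls **below 0.02** in any
population. All thresholds are strict inequalities as worded; the filter
is idempotent and its report reconciles input = surviving + removed.

Expected heterozygosity uses the small-sample unbiased estimator
He = 2p(1−p)·2n/(2n−1); observed Ho is the fraction of heterozygous
calls; per-population means are taken over loci with defined values.

## Outlier scans

**Weir–Cockerham θ.** Per-locus variance components a (among groups),
b (among individuals within groups) and c (within individuals) are
computed from genotype counts; θ = a/(a+b+c). The same components serve
the multi-population scan, the two-class marker tests and the
ratio-of-sums window F_ST. Monomorphic loci are reported absent; θ may
be slightly negative by construction.

**Trimmed-F_ST null.** The chi-square-family null is fitted not to the
bias-corrected θ but to the *uncorrected* ratio s²/(p̄(1−p̄)) of the
among-population frequency variance to the pooled heterozygosity scale —
the finite-sample correction in θ destroys the chi-square shape the
model assumes (this mirrors the convention of the tool this scan
emulates, which likewise fits its null on uncorrected F_ST). The model
is `F·df/F̄ ~ χ²(df)`; (F̄, df) are estimated by maximising the
truncated chi-square likelihood of the central mass remaining after
trimming 5% of loci on each side, with a bounded 1-D search over df
(tolerance 1e-6) and the mean profiled in an inner bounded search.
Loci with He < 0.1 are excluded from inference but still scored.
Right-tail p-values come from the fitted null; the genomic inflation
factor of the fitted statistics is reported as a diagnostic but not
applied a second time — the ML fit *is* the calibration, and on null
simulations re-scaling by a median-based λ measurably breaks the
uniformity the fit achieves.

**PCA communality.** Loci are mean-imputed, centred and scaled by the
binomial allele-frequency standard deviation; the top k = 3 principal
components of individuals are taken from the SVD. Each locus's
regression on the k components yields t-statistics, which are mapped
through their exact Student-t null (n−k−1 df) to normal scores before
the robust Mahalanobis step — at n ≈ 120 the raw t tails would inflate
the statistic by a few percent, which a median-based inflation factor
cannot repair. The Mahalanobis distance uses a
minimum-covariance-determinant estimate (ordinary covariance below 200
loci), is divided by the genomic inflation factor
λ = median(d²)/median(χ²₃), and referred to χ²₃.

**Bayesian F_ST decomposition.** The locus-by-population coefficient is
`F_ST(i,j) = expit(α_i + β_j)` (positive α = excess differentiation);
allele counts are beta-binomial with ancestral frequency μ_i and
precision t = (1−F)/F, which integrates the latent population
frequencies out analytically. A Metropolis-within-Gibbs sampler updates
μ (logit random walk), α (random walk, included loci), β (componentwise,
evaluated jointly — columns are conditionally independent), and a
reversible-jump move that toggles each α_i between zero and a draw from
its N(0, 2²) prior (so proposal and prior densities cancel and the
acceptance ratio is the likelihood ratio times the 1:10 prior odds).
Pilot runs adapt the random-walk scales toward 15–35% acceptance.
Posterior inclusion probabilities give Bayes factors against the prior
odds and q-values by cumulative posterior error; a locus is flagged at
BF ≥ 3 *and* q ≤ 0.1. Desk-scale chain lengths (2 pilots × 1,000;
5,000 burn-in; 5,000 kept, thinned by 5) are the defaults; the
field-standard long settings remain available through configuration.
With zero kept iterations the posterior inclusion equals the prior and
BF = 1 exactly.

**FDR and consensus.** Benjamini–Yekutieli step-up with the harmonic-sum
correction c(m) = Σ 1/i controls the two p-value methods at level 0.05
(the correction is stated without a level in the source procedure; the
level is a configuration knob). The consensus set keeps loci flagged by
at least two methods — the intersection property guarantees its
false-positive count never exceeds any single method's.

## Phenotype-class window scan

Within each ecotype, fish are ranked per population on a trait and split
evenly into low/high classes (odd counts: the median fish goes low; value
ties break by fish id, so the split is deterministic). Loci genotyped in
≥ 75% of the ecotype's fish are kept. Per marker: a two-sided Fisher
exact test on the 2×2 low/high × ref/alt allele-count table (vectorised
hypergeometric enumeration, verified against scipy per table) and the
two-group Weir–Cockerham θ. Windows are 10 kb wide, stepped every 200 bp,
0-based half-open and anchored at position 0 of each chromosome; windows
without markers are not emitted. Window F_ST is the ratio of summed
variance components (ratio-of-sums; the mean-of-ratios alternative is a
config switch), and the combined p-value is Stouffer's weighted z with
w_i = √(called fish at marker i), the standard weight for this
combination. Marker p-values are clamped to [1e-300, 1−1e-16] before the
z-transform: Fisher p-values of exactly 1 (monomorphic markers) would
otherwise map to −∞. BY-FDR over all emitted windows sets significance.
A Lindley local-score segmentation (h_i = −log10 p_i − ξ, ξ = 2 by
default, L_i = max(0, L_{i−1}+h_i)) is available as the
linkage-aware alternative aggregation.

The temperature association ranks loci by the p-value of the per-locus
OLS of minor allele frequency on mean summer stream temperature. The
minor allele is defined once from the pooled metapopulation and its
frequency tracked per population — folding to the within-population
minor allele would destroy exactly the monotone clinal profile the
regression looks for. Mantel tests (Pearson r of off-diagonal upper
triangles, label permutations, one-sided "greater" by default) relate
pairwise linearised F_ST/(1−F_ST) to fluvial distance or temperature
differences. Structure PCA mean-imputes missing calls, centres, and
fixes component signs by making the largest-magnitude loading positive.

## Synthetic cohorts and planted truth

The generator emulates the study design: six demes in three ecotype
pairs with mean summer temperatures (19.1, 19.1, 16.8, 16.8, 14.0,
14.0) °C, reproducing the reported ecotype offsets (+2.3 °C desert vs
cool montane, +5.1 °C vs cold montane); 20 fish per deme; 20,000 loci on
29 chromosomes of 7 Mb in RAD-style tags of 1–4 SNPs within 75 bp
(tag-count mix 65/20/10/5%, ≈ 1.55 SNPs per tag); 5%
missing-completely-at-random calls.

* **Neutral structure** is Balding–Nichols: per-deme allele frequencies
  are beta draws around a U[0.05, 0.95] ancestral frequency with a
  single parameter targeting F_ST = 0.05 (moderate salmonid-scale
  differentiation); genotypes are binomial.
* **Clines.** 50 causal loci receive a logit-scale shift of
  slope/0.25 per °C of deviation from the mean deme temperature, so the
  nominal slope is the frequency change per °C at p = 0.5; frequencies
  are clipped to [0.01, 0.99] and clipping is logged. The default slope
  of 0.2/°C sweeps a locus from rare to common across the ~5 °C span —
  the near-fixation desert-versus-montane contrast the study's
  temperature-associated outliers show in their heterozygosity table.
  Causal ancestral frequencies are drawn from U[0.2, 0.8]: divergent
  selection with migration maintains such loci at intermediate
  metapopulation frequency.
* **Phenotypes.** Each fish's trial follows a two-segment Arrhenius
  curve — 97.7 bpm at 15 °C, Q10 1.8 below the breakpoint (19.6 °C) and
  1.4 above, peak at 23 °C — with either a 9 bpm/°C post-peak decline or
  an arrhythmia at the peak (50/50 by default), plus 2 bpm Gaussian
  observation noise per step. These defaults reproduce the scale and
  ordering of the published population means. Genetic values are
  additive over causal genotypes (0.45 bpm, 0.04 °C and 0.02 °C per
  allele copy on the rate, breakpoint and peak traits) and enter the
  curve as offsets on the trait scale, so regressing derived traits on
  true genetic values recovers slope 1 at zero noise. Because clinal
  allele frequencies rise with temperature, desert fish inherit higher
  rates without any explicit ecotype term. T_PEAK is observed on the
  1 °C ladder, so its genetic variation is quantised to whole degrees;
  the slope-1 recovery check therefore uses the continuous traits.
* **Temperature series** are seasonal + diurnal cosines plus Gaussian
  noise at a 25–30 min logger cadence.

What the generator does *not* emulate: linkage disequilibrium beyond
the perfect within-tag association, non-MCAR missingness (allele
dropout), genotyping error, HWE departures within demes, kinship, and
selection on phenotype within a generation. Passing tests therefore
demonstrate correctness and calibration of the *procedures* under the
island-model assumptions, not robustness to those real-data artefacts.

## Replicate studies (problem sizes)

The studies behind the acceptance checks are sized to finish on one CPU
in minutes, as the package's own scale choices:

* **Null calibration**: 20 no-selection replicates at the full default
  panel (6 × 20 × 20,000). KS uniformity is evaluated on the loci each
  method calibrates (He ≥ 0.1 for the trimmed null; all scored loci for
  PCA); the Bayesian method reports Bayes factors, not p-values, so its
  null behaviour is checked by the fraction flagged under pure drift at
  its own example scale instead.
* **Consensus power**: 20 replicates on a 2,000-locus panel with 20
  planted clinal loci and all three methods running (short-chain MCMC:
  1 × 500 pilot, 1,500 burn-in, 2,000 kept thinned by 4); the smaller
  panel is what lets the MCMC participate in every replicate.
* **Window power**: 20 replicates, one ecotype (2 × 20 fish), 20,000
  markers, five causal *tags* planted with low/high class frequencies
  0.15/0.85. Planting acts on whole tags because tag-mate SNPs sit
  within 75 bp and co-segregate; a class allele-frequency difference of
  0.7 is what "strongly associated" must mean at these sample sizes —
  at a difference of 0.4 a single marker's Fisher p (~1e-4 with 40
  alleles per class) cannot clear BY-FDR over ~10⁵ emitted windows.
* **Cardiac recovery**: noiseless single-trial inversion plus 200 noisy
  trials at 2 bpm.

## Known limitations

* The trimmed-null fit assumes one shared null family across loci;
  strong He-dependence of drift (e.g., widely varying sample sizes per
  locus) would violate it.
* The short-chain MCMC defaults trade posterior precision for runtime;
  inclusion probabilities near the BF = 3 boundary wobble between runs
  with different seeds (the long settings are one config change away).
* Window p-values of overlapping windows are strongly dependent; BY-FDR
  is valid under that dependence but conservative, and the discrete
  Fisher p-values add further conservatism — null window-significance
  rates run far below nominal.
* With six populations, the temperature regression has four residual
  degrees of freedom; it ranks candidates within the outlier set but
  has little absolute power, exactly as in the source analysis.
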