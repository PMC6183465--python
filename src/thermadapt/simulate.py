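"""Synthetic genotypes, stream temperatures and cardiac trials with planted truth.

The generator emulates the statistical structure the downstream analyses
assume for six stream-resident populations in three thermal ecotype pairs
(desert, cool montane, cold montane):

* neutral island-model genotypes: ancestral allele frequencies drawn
  uniformly, per-population frequencies by a Balding–Nichols beta draw
  whose single parameter sets baseline F_ST, genotypes binomial, and
  missingness injected completely at random;
* a minority of causal loci whose allele frequency follows a cline in mean
  summer stream temperature (applied on the logit scale);
* polygenic cardiac phenotypes: per-fish genetic values are additive over
  causal genotypes and offset the parameters of a two-segment Arrhenius
  heart-rate curve with a breakpoint, a plateau, and either a sharp
  post-peak decline or an arrhythmia at the peak;
* logger-style stream temperature series: seasonal + diurnal sinusoids
  plus noise at a 25–30 minute cadence.

Everything is deterministic given the seed recorded in
:class:`SimulationTruth`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cardiac import ECGTrial, KELVIN_OFFSET
from .genotypes import MISSING, GenotypeMatrix, LOCUS_COLUMNS

log = logging.getLogger(__name__)

#: default mean summer stream temperatures (°C) for the six demes:
#: two desert, two cool montane, two cold montane streams, reproducing the
#: observed ecotype offsets (+2.3 °C desert vs cool, +5.1 °C desert vs cold).
DEFAULT_POP_TEMPS = (19.1, 19.1, 16.8, 16.8, 14.0, 14.0)
DEFAULT_POPS = ("desert_a", "desert_b", "cool_a", "cool_b", "cold_a", "cold_b")
DEFAULT_ECOTYPES = ("desert", "desert", "cool_montane", "cool_montane",
                    "cold_montane", "cold_montane")

#: default per-°C allele-frequency cline slope at p = 0.5 for causal loci;
#: over the ~5 °C span between desert and cold-montane streams this sweeps a
#: locus from rare to common, matching the near-fixation differentiation
#: seen at temperature-associated outliers.
DEFAULT_CLINE_SLOPE = 0.2

N_CHROMS = 29
CHROM_LENGTH_BP = 7_000_000


@dataclass
class SimulationTruth:
    """Planted ground truth for parameter-recovery tests."""

    causal_locus_ids: list[str]
    cline_slopes: np.ndarray          # per causal locus, freq/°C at p = 0.5
    phenotype_effects: pd.DataFrame   # causal loci x traits (fh, t_ab, t_peak)
    neutral_fst_target: float
    seed: int

    def save(self, path) -> None:
        """Plain-text key-value sidecar plus per-locus effect table."""
        with open(path, "w") as fh:
            fh.write(f"neutral_fst_target\t{self.neutral_fst_target}\n")
            fh.write(f"seed\t{self.seed}\n")
            fh.write(f"n_causal\t{len(self.causal_locus_ids)}\n")
            fh.write("locus_id\tcline_slope\t" +
                     "\t".join(self.phenotype_effects.columns) + "\n")
            for lid, slope, (_, eff) in zip(
                self.causal_locus_ids, self.cline_slopes,
                self.phenotype_effects.iterrows(),
            ):
                fh.write(f"{lid}\t{slope}\t" +
                         "\t".join(str(v) for v in eff.to_numpy()) + "\n")

    @classmethod
    def load(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            header = {}
            for _ in range(3):
                k, v = fh.readline().rstrip("\n").split("\t")
                header[k] = v
            table = pd.read_csv(fh, sep="\t")
        effects = table.drop(columns=["locus_id", "cline_slope"])
        return cls(
            causal_locus_ids=table["locus_id"].astype(str).tolist(),
            cline_slopes=table["cline_slope"].to_numpy(),
            phenotype_effects=effects,
            neutral_fst_target=float(header["neutral_fst_target"]),
            seed=int(header["seed"]),
        )


@dataclass
class TemperatureSeries:
    """A stream temperature-logger record at 25–30 minute cadence."""

    stream_id: str
    timestamps: pd.DatetimeIndex
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if len(self.timestamps) != len(self.temp_c):
            raise ValueError("timestamps and temperatures differ in length")
        if len(self.timestamps) and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if np.any((self.temp_c <= -1) | (self.temp_c >= 40)):
            raise ValueError("temperatures outside plausible (-1, 40) °C range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stream_id": self.stream_id,
            "timestamp": self.timestamps,
            "temp_c": self.temp_c,
        })


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def default_truth(
    n_loci: int = 20_000,
    n_causal: int = 50,
    cline_slope: float = DEFAULT_CLINE_SLOPE,
    neutral_fst_target: float = 0.05,
    effect_fh_bpm: float = 0.45,
    effect_t_ab_c: float = 0.04,
    effect_t_peak_c: float = 0.02,
    seed: int = 0,
) -> SimulationTruth:
    """Planted truth at the default study scale.

    Causal loci are spread evenly through the locus index so they land on
    distinct tags/windows; cline slopes alternate in sign; additive
    phenotype effects (per alternate-allele copy) act on maximum heart rate
    (bpm, shared by the 20 °C and peak phenotypes), the Arrhenius
    breakpoint and the peak temperature (°C).
    """
    if not 0 <= n_causal < n_loci:
        raise ValueError("n_causal must be in [0, n_loci)")
    idx = (np.linspace(0, n_loci - 1, n_causal).astype(int) if n_causal
           else np.array([], dtype=int))
    signs = np.where(np.arange(n_causal) % 2 == 0, 1.0, -1.0)
    effects = pd.DataFrame({
        "fh": signs * effect_fh_bpm,
        "t_ab": signs * effect_t_ab_c,
        "t_peak": signs * effect_t_peak_c,
    })
    return SimulationTruth(
        causal_locus_ids=[f"L{i:06d}" for i in idx],
        cline_slopes=signs * cline_slope,
        phenotype_effects=effects,
        neutral_fst_target=neutral_fst_target,
        seed=seed,
    )


def simulate_island_genotypes(
    n_pops: int = 6,
    n_per_pop: int = 20,
    n_loci: int = 20_000,
    truth: Optional[SimulationTruth] = None,
    pop_temps: Sequence[float] = DEFAULT_POP_TEMPS,
    pop_names: Sequence[str] = DEFAULT_POPS,
    ecotypes: Sequence[str] = DEFAULT_ECOTYPES,
    missing_rate: float = 0.05,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    causal_ancestral_range: tuple[float, float] = (0.2, 0.8),
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Island-model genotypes with planted temperature clines.

    Ancestral allele frequencies are uniform on ``ancestral_range``
    (causal loci on ``causal_ancestral_range``: divergent selection keeps
    them at intermediate metapopulation frequency).  Per-population
    frequencies follow a Balding–Nichols beta draw parameterised by
    ``truth.neutral_fst_target``; causal loci receive an additional shift
    of ``cline_slope * (pop_temp - mean_temp) / 0.25`` on the logit scale
    (so the slope is the frequency change per °C at p = 0.5), and the
    resulting frequencies are clipped to [0.01, 0.99].  Genotypes are
    binomial(2, p); missingness is injected completely at random.

    Loci are grouped into RAD-style tags carrying 1–4 SNPs within 75 bp,
    and tags are placed uniformly on 29 chromosomes so that every causal
    locus has a mapped position.
    """
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    if n_loci < 100:
        raise ValueError("need at least 100 loci")
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be positive")
    if len(pop_temps) != n_pops:
        raise ValueError("pop_temps length must equal n_pops")
    if truth is None:
        truth = default_truth(n_loci=n_loci)
    rng = np.random.default_rng(truth.seed)
    pop_temps = np.asarray(pop_temps, dtype=float)
    pop_names = list(pop_names)[:n_pops]
    ecotypes = list(ecotypes)[:n_pops]

    locus_ids = np.array([f"L{i:06d}" for i in range(n_loci)])
    causal_mask = np.isin(locus_ids, truth.causal_locus_ids)
    if causal_mask.sum() != len(truth.causal_locus_ids):
        raise ValueError("truth names causal loci outside the simulated panel")

    lo, hi = ancestral_range
    p_anc = rng.uniform(lo, hi, size=n_loci)
    clo, chi = causal_ancestral_range
    p_anc[causal_mask] = rng.uniform(clo, chi, size=int(causal_mask.sum()))

    fst = truth.neutral_fst_target
    if fst > 0:
        shape = (1 - fst) / fst
        a = np.maximum(p_anc * shape, 1e-9)
        b = np.maximum((1 - p_anc) * shape, 1e-9)
        pop_freqs = rng.beta(a, b, size=(n_pops, n_loci))
    else:
        pop_freqs = np.tile(p_anc, (n_pops, 1))

    # temperature clines on the logit scale
    dtemp = pop_temps - pop_temps.mean()
    slopes = np.zeros(n_loci)
    slopes[causal_mask] = np.asarray(truth.cline_slopes)
    if causal_mask.any():
        shift = np.outer(dtemp, slopes / 0.25)  # d expit/dx = 0.25 at p = 0.5
        eps = 1e-12
        base = np.clip(pop_freqs, eps, 1 - eps)
        shifted = _expit(_logit(base) + shift)
        n_extreme = int(((shifted[:, causal_mask] < 0.01) |
                         (shifted[:, causal_mask] > 0.99)).sum())
        if n_extreme:
            log.info("cline pushed %d pop-locus frequencies past [0.01, 0.99]; "
                     "clipped", n_extreme)
        pop_freqs = np.where(slopes != 0, shifted, pop_freqs)
    pop_freqs = np.clip(pop_freqs, 0.01, 0.99)

    n_ind = n_pops * n_per_pop
    calls = np.empty((n_ind, n_loci), dtype=np.int8)
    for j in range(n_pops):
        block = slice(j * n_per_pop, (j + 1) * n_per_pop)
        calls[block] = rng.binomial(2, pop_freqs[j], size=(n_per_pop, n_loci))
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING

    # RAD-style tag layout: 1-4 SNPs per 75-bp tag, tags uniform on chromosomes
    snps_per_tag = rng.choice([1, 2, 3, 4], size=n_loci,
                              p=[0.65, 0.20, 0.10, 0.05])
    counts = np.cumsum(snps_per_tag)
    n_tags = int(np.searchsorted(counts, n_loci) + 1)
    tag_of_locus = np.repeat(np.arange(n_tags), snps_per_tag[:n_tags])[:n_loci]
    tag_chrom = rng.integers(1, N_CHROMS + 1, size=n_tags)
    tag_start = rng.integers(0, CHROM_LENGTH_BP - 100, size=n_tags)
    first_of_tag = np.concatenate(([0], np.cumsum(snps_per_tag[:n_tags])))
    rank_in_tag = np.arange(n_loci) - first_of_tag[tag_of_locus]
    offset_in_tag = rank_in_tag * 18 + rng.integers(0, 18, size=n_loci)
    chrom = np.array([f"chr{c}" for c in tag_chrom[tag_of_locus]])
    pos = tag_start[tag_of_locus] + offset_in_tag

    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_loci)
    alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, n_loci)) % 4]

    loci = pd.DataFrame({
        "locus_id": locus_ids,
        "tag_id": np.array([f"tag{t:06d}" for t in tag_of_locus]),
        "chrom": chrom,
        "pos_bp": pos.astype(np.int64),
        "ref": ref,
        "alt": alt,
    })[LOCUS_COLUMNS]
    individuals = pd.DataFrame({
        "individual_id": [f"{pop_names[j]}_f{i:02d}"
                          for j in range(n_pops) for i in range(n_per_pop)],
        "population": np.repeat(pop_names, n_per_pop),
        "ecotype": np.repeat(ecotypes, n_per_pop),
    })
    return GenotypeMatrix(calls=calls, individuals=individuals, loci=loci), truth


def genetic_values(g: GenotypeMatrix, truth: SimulationTruth) -> pd.DataFrame:
    """Per-fish additive genetic values for each trait.

    Sums ``effect * (genotype - 2 * mean_freq)`` over causal loci (missing
    causal genotypes contribute their locus mean, i.e. zero deviation), so
    values are centred near zero in the metapopulation.
    """
    idx = g.loci.set_index("locus_id").index.get_indexer(truth.causal_locus_ids)
    present = idx >= 0
    idx = idx[present]
    calls = g.calls[:, idx].astype(float)
    called = calls != MISSING
    locus_mean = np.nanmean(np.where(called, calls, np.nan), axis=0)
    dose = np.where(called, calls, locus_mean[None, :]) - locus_mean[None, :]
    effects = truth.phenotype_effects.iloc[present]
    out = {}
    for trait in effects.columns:
        out[trait] = dose @ effects[trait].to_numpy()
    return pd.DataFrame(out, index=g.individuals["individual_id"])


# ---------------------------------------------------------------- trials

@dataclass
class TrialParams:
    """Shape of the simulated acute-warming heart-rate curve.

    Defaults reproduce field-scale values: ~98 bpm at 15 °C, a breakpoint
    near 19.6 °C where thermal sensitivity falls from Q10 ≈ 1.8 to ≈ 1.4,
    a peak near 23 °C, and either a sharp (> 5 bpm/°C) post-peak decline
    or an arrhythmia at the peak.
    """

    start_temp_c: float = 13.0
    f15_bpm: float = 97.7           # mass-corrected rate at 15 °C
    t_ab_c: float = 19.6
    t_peak_c: float = 23.0
    q10_below: float = 1.8          # thermal sensitivity below the breakpoint
    q10_above: float = 1.4          # between breakpoint and peak
    post_peak_drop_bpm: float = 9.0
    arrhythmia_at_peak: bool = False
    extra_steps_past_peak: int = 2


def _arrhenius_slope(q10_val: float, t_ref_c: float) -> float:
    """Slope of ln(rate) vs 1/K equivalent to a Q10 at ``t_ref_c``."""
    x1 = 1.0 / (t_ref_c + KELVIN_OFFSET)
    x2 = 1.0 / (t_ref_c + 10.0 + KELVIN_OFFSET)
    return np.log(q10_val) / (x2 - x1)


def simulate_cardiac_trial(
    fish_mass: float = 11.0,
    genetic_value: Optional[dict] = None,
    noise_sd: float = 0.0,
    trial_params: Optional[TrialParams] = None,
    fish_id: str = "fish",
    population: str = "pop",
    ecotype: str = "desert",
    rng: Optional[np.random.Generator] = None,
) -> ECGTrial:
    """Simulate one temperature-stepped trial.

    The underlying curve is two-segment Arrhenius (linear in ln f vs 1/K)
    with the breakpoint at ``t_ab + genetic offset`` and peak at
    ``t_peak + genetic offset``; past the peak the rate either drops by
    ``post_peak_drop_bpm`` per °C or an arrhythmia is flagged.  Gaussian
    observation noise (bpm) is added per step.  Rates are written on the
    raw scale for the given fish mass so that mass correction recovers the
    configured common-mass curve.
    """
    params = trial_params or TrialParams()
    gv = {"fh": 0.0, "t_ab": 0.0, "t_peak": 0.0}
    gv.update(genetic_value or {})
    rng = rng or np.random.default_rng(0)

    t_ab = params.t_ab_c + gv["t_ab"]
    t_peak = params.t_peak_c + gv["t_peak"]
    t_peak = round(t_peak)  # peaks are observed on the 1 °C ladder
    if not params.start_temp_c < t_ab < t_peak:
        raise ValueError("breakpoint must lie inside the temperature ladder")

    n_steps = int(t_peak - params.start_temp_c) + params.extra_steps_past_peak + 1
    temps = params.start_temp_c + np.arange(n_steps, dtype=float)

    s1 = _arrhenius_slope(params.q10_below, 15.0)
    s2 = _arrhenius_slope(params.q10_above, 15.0)
    x = 1.0 / (temps + KELVIN_OFFSET)
    x15 = 1.0 / (15.0 + KELVIN_OFFSET)
    x_ab = 1.0 / (t_ab + KELVIN_OFFSET)
    ln_f15 = np.log(params.f15_bpm)
    ln_f = np.where(
        temps <= t_ab,
        ln_f15 + s1 * (x - x15),
        ln_f15 + s1 * (x_ab - x15) + s2 * (x - x_ab),
    )
    # the heart-rate genetic value is an additive bpm offset on the whole
    # curve, so simulated rate phenotypes track it with unit slope
    rates = np.exp(ln_f) + gv["fh"]

    arrhythmia = np.zeros(n_steps, dtype=bool)
    past = temps > t_peak
    if params.arrhythmia_at_peak:
        # the arrhythmic beat appears at the peak step itself; recorded rate
        # stays at the plateau value so the peak temperature is preserved
        i_peak = int(np.flatnonzero(temps == t_peak)[0])
        peak_rate = rates[i_peak]
        arrhythmia[i_peak + 1:] = True
        rates[past] = peak_rate * 0.9
        arrhythmia[i_peak] = True
        rates[i_peak] = peak_rate + 0.5   # plateau max falls on the flagged step
    else:
        i_peak = int(np.flatnonzero(temps == t_peak)[0])
        drop = params.post_peak_drop_bpm * (temps[past] - t_peak)
        rates[past] = np.maximum(rates[i_peak] - drop, 1.0)

    if noise_sd > 0:
        noisy = rates + rng.normal(0.0, noise_sd, size=n_steps)
        rates = np.maximum(noisy, 1.0)

    raw = rates * (fish_mass / 11.0) ** (-0.1)   # invert the mass correction
    return ECGTrial(
        fish_id=fish_id, population=population, ecotype=ecotype,
        mass_g=fish_mass, temps_c=temps, fhmax_bpm=raw, arrhythmia=arrhythmia,
    )


def simulate_cohort_trials(
    g: GenotypeMatrix,
    truth: SimulationTruth,
    noise_sd: float = 2.0,
    arrhythmia_frac: float = 0.5,
    mass_range_g: tuple[float, float] = (3.0, 15.0),
    trial_params: Optional[TrialParams] = None,
    seed: Optional[int] = None,
) -> list[ECGTrial]:
    """One trial per genotyped fish, with phenotypes tied to causal loci."""
    base = trial_params or TrialParams()
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    gvals = genetic_values(g, truth)
    trials = []
    for i, row in g.individuals.iterrows():
        gv = gvals.loc[row["individual_id"]].to_dict()
        params = TrialParams(**{**base.__dict__,
                                "arrhythmia_at_peak": rng.random() < arrhythmia_frac})
        trials.append(simulate_cardiac_trial(
            fish_mass=float(rng.uniform(*mass_range_g)),
            genetic_value=gv,
            noise_sd=noise_sd,
            trial_params=params,
            fish_id=row["individual_id"],
            population=row["population"],
            ecotype=row["ecotype"],
            rng=rng,
        ))
    return trials


# ---------------------------------------------------------------- streams

@dataclass
class RegimeParams:
    """Configuration for a synthetic stream-temperature series."""

    stream_id: str = "stream"
    mean_c: float = 16.0             # annual (or window) mean level
    seasonal_amplitude_c: float = 6.0
    diurnal_amplitude_c: float = 2.0  # half the diurnal range
    noise_sd_c: float = 0.3
    start: str = "2015-06-01"
    end: str = "2015-09-30"
    cadence_min: int = 27            # logger cadence, within 25-30 min
    peak_day_of_year: int = 213      # seasonal maximum (early August)
    seed: int = 0


def simulate_temperature_series(params: RegimeParams) -> TemperatureSeries:
    """Seasonal + diurnal sinusoids plus noise at logger cadence.

    With zero noise the daily range equals ``2 * diurnal_amplitude_c`` and
    the mean over any whole day equals the seasonal component that day.
    """
    ts = pd.date_range(params.start, params.end, freq=f"{params.cadence_min}min")
    if len(ts) == 0:
        raise ValueError("empty date range")
    rng = np.random.default_rng(params.seed)
    doy = ts.dayofyear.to_numpy() + ts.hour.to_numpy() / 24.0
    hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    seasonal = params.seasonal_amplitude_c * np.cos(
        2 * np.pi * (doy - params.peak_day_of_year) / 365.25
    )
    diurnal = params.diurnal_amplitude_c * np.cos(2 * np.pi * (hour - 16.0) / 24.0)
    temp = params.mean_c + seasonal + diurnal
    if params.noise_sd_c > 0:
        temp = temp + rng.normal(0, params.noise_sd_c, size=len(ts))
    return TemperatureSeries(stream_id=params.stream_id, timestamps=ts,
                             temp_c=np.clip(temp, -0.9, 39.9))


# ------------------------------------------------- planted class association

def plant_class_association(
    g: GenotypeMatrix,
    fish_index: np.ndarray,
    labels: np.ndarray,
    causal_loci: np.ndarray,
    freq_low: float = 0.15,
    freq_high: float = 0.85,
    seed: int = 0,
) -> GenotypeMatrix:
    """Overwrite genotypes at ``causal_loci`` so the low/high phenotype
    classes differ in allele frequency by ``freq_high - freq_low``.

    Used by power experiments for the phenotype-class window scan; returns
    a copy of ``g`` with the planted columns replaced.
    """
    rng = np.random.default_rng(seed)
    calls = g.calls.copy()
    labels = np.asarray(labels)
    for locus in np.atleast_1d(causal_loci):
        p = np.where(labels == 1, freq_high, freq_low)
        calls[fish_index, locus] = rng.binomial(2, p).astype(calls.dtype)
    return GenotypeMatrix(calls=calls, individuals=g.individuals.copy(),
                          loci=g.loci.copy())
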