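"""Cardiac thermal-performance phenotypes from acute-warming heart-rate trials.

During an acute-warming trial, water temperature is stepped 1 °C at a time
while the fish's pharmacologically stimulated maximum heart rate (f_h,max,
beats per minute) is recorded at each step, together with a flag marking
cardiac arrhythmia.  Four phenotypes summarise each trial:

* ``fh20``    -- mass-corrected f_h,max at the 20 °C step,
* ``fh_peak`` -- mass-corrected peak f_h,max,
* ``t_ab``    -- Arrhenius breakpoint temperature: the temperature at which
  the slope of ln(f_h,max) against inverse Kelvin temperature changes,
  estimated as the intersection of two least-squares lines,
* ``t_peak``  -- the temperature of peak f_h,max, reached either when the
  rate drops sharply (> 5 bpm over 1 °C of warming) or when an arrhythmia
  develops,

plus ``q10``, the temperature coefficient of f_h,max from the 15 °C step to
the peak.  Heart rates are corrected to a common body mass (11 g by default)
with a mass exponent of -0.1 before phenotypes are derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

KELVIN_OFFSET = 273.15

#: default reference mass (g) heart rates are corrected to
REF_MASS_G = 11.0
#: default allometric mass exponent for heart rate
MASS_EXPONENT = -0.1
#: default trigger for a "dramatic" rate drop (bpm over one 1 °C step)
DROP_THRESHOLD_BPM = 5.0

ECOTYPES = ("desert", "cool_montane", "cold_montane")


@dataclass
class ECGTrial:
    """One fish's ordered temperature-stepped maximum-heart-rate record."""

    fish_id: str
    population: str
    ecotype: str
    mass_g: float
    temps_c: np.ndarray        # strictly increasing test temperatures, °C
    fhmax_bpm: np.ndarray      # raw (not mass-corrected) rates, bpm
    arrhythmia: np.ndarray     # boolean flags per step

    def __post_init__(self) -> None:
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        self.fhmax_bpm = np.asarray(self.fhmax_bpm, dtype=float)
        self.arrhythmia = np.asarray(self.arrhythmia, dtype=bool)
        if not (len(self.temps_c) == len(self.fhmax_bpm) == len(self.arrhythmia)):
            raise ValueError("trial step arrays must have equal length")
        if np.any(np.diff(self.temps_c) <= 0):
            raise ValueError("test temperatures must be strictly increasing")
        if self.mass_g <= 0:
            raise ValueError("mass_g must be positive")
        ok = ~self.arrhythmia
        if np.any(self.fhmax_bpm[ok] <= 0):
            raise ValueError("fhmax_bpm must be positive for non-arrhythmic steps")

    @property
    def n_steps(self) -> int:
        return len(self.temps_c)


@dataclass
class CardiacSummary:
    """Derived thermal-performance phenotypes for one fish.

    Absent phenotypes (e.g. no Arrhenius breakpoint for a single-phase
    curve, or no 20 °C step in the ladder) are ``None``.
    """

    fish_id: str
    population: str = ""
    ecotype: str = ""
    fh20: Optional[float] = None
    fh_peak: Optional[float] = None
    t_ab: Optional[float] = None
    t_peak: Optional[float] = None
    q10: Optional[float] = None
    peak_cause: str = "end_of_trial"


def mass_correct(
    fh: float,
    mass_g: float,
    ref_mass_g: float = REF_MASS_G,
    exponent: float = MASS_EXPONENT,
) -> float:
    """Correct a heart rate to a common body mass.

    ``corrected = fh * (mass_g / ref_mass_g) ** (-exponent)``; with the
    default negative exponent a fish heavier than the reference is corrected
    upward.  Accepts scalars or arrays.
    """
    fh = np.asarray(fh, dtype=float)
    if np.any(fh <= 0):
        raise ValueError("heart rate must be positive")
    if mass_g <= 0 or ref_mass_g <= 0:
        raise ValueError("masses must be positive")
    out = fh * (mass_g / ref_mass_g) ** (-exponent)
    return float(out) if out.ndim == 0 else out


def detect_peak(
    trial: ECGTrial, drop_threshold: float = DROP_THRESHOLD_BPM
) -> tuple[float, float, str]:
    """Locate peak f_h,max and its temperature.

    Scans steps in temperature order and triggers at the first step whose
    rate falls more than ``drop_threshold`` bpm below the preceding step's
    rate (strict inequality), or at the first arrhythmic step, whichever
    comes first.  ``t_peak`` is the temperature of the maximum recorded rate
    at or before the trigger; ``fh_peak`` is the maximum *non-arrhythmic*
    rate at or before the trigger.  Without a trigger the cause is
    ``end_of_trial``.  Returned rates are raw (not mass-corrected).
    """
    if trial.n_steps < 3:
        raise ValueError("need at least 3 steps to detect a peak")
    if np.all(trial.arrhythmia):
        raise ValueError("all steps arrhythmic; no usable rates")

    trigger = trial.n_steps - 1
    cause = "end_of_trial"
    for i in range(trial.n_steps):
        if trial.arrhythmia[i]:
            trigger, cause = i, "arrhythmia"
            break
        if i > 0 and trial.fhmax_bpm[i - 1] - trial.fhmax_bpm[i] > drop_threshold:
            trigger, cause = i, "rate_drop"
            break

    upto = slice(0, trigger + 1)
    t_peak = float(trial.temps_c[upto][np.argmax(trial.fhmax_bpm[upto])])
    ok = ~trial.arrhythmia[upto]
    fh_peak = float(np.max(trial.fhmax_bpm[upto][ok]))
    return fh_peak, t_peak, cause


def q10(f1: float, t1: float, f2: float, t2: float) -> float:
    """Temperature coefficient ``Q10 = (f2/f1) ** (10 / (t2 - t1))``."""
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if f1 <= 0 or f2 <= 0:
        raise ValueError("rates must be positive")
    return (f2 / f1) ** (10.0 / (t2 - t1))


def _segment_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b x; returns (a, b, rss)."""
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    return a, b, float(resid @ resid)


def fit_arrhenius_breakpoint(
    trial: ECGTrial,
    min_points_per_segment: int = 3,
    t_peak: Optional[float] = None,
    slope_tol: float = 1e-3,
) -> tuple[Optional[float], tuple[float, float], float]:
    """Arrhenius breakpoint temperature from a two-line fit.

    Transforms steps up to and including ``t_peak`` (detected if not given)
    to an Arrhenius plot, x = 1/(T + 273.15), y = ln f_h,max, then searches
    every split leaving at least ``min_points_per_segment`` points per
    segment, fits ordinary least squares to each side, and keeps the split
    minimising the total residual sum of squares.  The breakpoint is the °C
    temperature at the intersection of the two fitted lines.

    Returns ``(t_ab, (slope_lo, slope_hi), rss)``; ``t_ab`` is ``None`` when
    the data cannot support a breakpoint (too few points, near-equal segment
    slopes, or an intersection outside the fitted temperature range).
    Slopes are on the Arrhenius scale (d ln f / d (1/K)), low-temperature
    segment first.
    """
    if t_peak is None:
        _, t_peak, _ = detect_peak(trial)
    use = (trial.temps_c <= t_peak + 1e-9) & ~trial.arrhythmia
    temps = trial.temps_c[use]
    rates = trial.fhmax_bpm[use]
    if len(temps) < 3:
        raise ValueError("fewer than 3 usable steps for the Arrhenius fit")
    if len(temps) < 2 * min_points_per_segment:
        return None, (math.nan, math.nan), math.nan

    x = 1.0 / (temps + KELVIN_OFFSET)   # decreasing with temperature
    y = np.log(rates)

    best: Optional[tuple[float, tuple, tuple]] = None   # (rss, lo_fit, hi_fit)
    for split in range(min_points_per_segment, len(x) - min_points_per_segment + 1):
        a1, b1, r1 = _segment_ols(x[:split], y[:split])
        a2, b2, r2 = _segment_ols(x[split:], y[split:])
        if best is None or r1 + r2 < best[0]:
            best = (r1 + r2, (a1, b1), (a2, b2))

    assert best is not None
    rss, (a_lo, b_lo), (a_hi, b_hi) = best
    # x[:split] covers the *low* temperatures? x decreases with T, and temps
    # ascend, so x[:split] is the high-x / low-temperature side.
    if abs(b_lo - b_hi) < slope_tol * max(1.0, abs(b_lo), abs(b_hi)):
        return None, (b_lo, b_hi), rss      # single-phase curve
    x_int = (a_hi - a_lo) / (b_lo - b_hi)
    if x_int <= 0:
        return None, (b_lo, b_hi), rss
    t_ab = 1.0 / x_int - KELVIN_OFFSET
    if not (temps[0] - 1e-6 <= t_ab <= temps[-1] + 1e-6):
        return None, (b_lo, b_hi), rss
    return float(t_ab), (b_lo, b_hi), rss


def _step_at(trial: ECGTrial, temp: float, tol: float = 0.5) -> Optional[int]:
    """Index of the ladder step nearest ``temp`` within ``tol`` °C."""
    d = np.abs(trial.temps_c - temp)
    i = int(np.argmin(d))
    return i if d[i] <= tol else None


def summarize_trial(
    trial: ECGTrial,
    ref_mass_g: float = REF_MASS_G,
    exponent: float = MASS_EXPONENT,
    drop_threshold: float = DROP_THRESHOLD_BPM,
) -> CardiacSummary:
    """Derive all cardiac phenotypes for one trial (rates mass-corrected)."""
    fh_peak_raw, t_peak, cause = detect_peak(trial, drop_threshold)
    fh_peak = mass_correct(fh_peak_raw, trial.mass_g, ref_mass_g, exponent)

    summary = CardiacSummary(
        fish_id=trial.fish_id,
        population=trial.population,
        ecotype=trial.ecotype,
        fh_peak=fh_peak,
        t_peak=t_peak,
        peak_cause=cause,
    )

    i20 = _step_at(trial, 20.0)
    if i20 is not None and not trial.arrhythmia[i20]:
        summary.fh20 = mass_correct(
            trial.fhmax_bpm[i20], trial.mass_g, ref_mass_g, exponent
        )
    else:
        log.info("fish %s: no usable 20 °C step; fh20 absent", trial.fish_id)

    i15 = _step_at(trial, 15.0)
    if i15 is not None and not trial.arrhythmia[i15] and t_peak > trial.temps_c[i15]:
        summary.q10 = q10(
            trial.fhmax_bpm[i15], trial.temps_c[i15], fh_peak_raw, t_peak
        )
    else:
        log.info("fish %s: no usable 15 °C step; q10 absent", trial.fish_id)

    try:
        t_ab, _, _ = fit_arrhenius_breakpoint(trial, t_peak=t_peak)
    except ValueError:
        t_ab = None
    summary.t_ab = t_ab
    return summary


# ---------------------------------------------------------------- I/O

TRIAL_COLUMNS = [
    "fish_id", "population", "ecotype", "mass_g", "temp_c", "fhmax_bpm", "arrhythmia",
]


def write_trials(trials: Sequence[ECGTrial], path) -> None:
    """Write trials as a tidy tab-separated table, one row per step."""
    rows = []
    for t in trials:
        for temp, fh, arr in zip(t.temps_c, t.fhmax_bpm, t.arrhythmia):
            rows.append((t.fish_id, t.population, t.ecotype, t.mass_g,
                         temp, fh, int(arr)))
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_trials(path) -> list[ECGTrial]:
    """Read trials from the tidy tab-separated format of :func:`write_trials`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials = []
    for fish_id, grp in df.groupby("fish_id", sort=False):
        grp = grp.sort_values("temp_c")
        trials.append(ECGTrial(
            fish_id=str(fish_id),
            population=str(grp["population"].iloc[0]),
            ecotype=str(grp["ecotype"].iloc[0]),
            mass_g=float(grp["mass_g"].iloc[0]),
            temps_c=grp["temp_c"].to_numpy(),
            fhmax_bpm=grp["fhmax_bpm"].to_numpy(),
            arrhythmia=grp["arrhythmia"].to_numpy().astype(bool),
        ))
    return trials


def summaries_to_frame(summaries: Sequence[CardiacSummary]) -> pd.DataFrame:
    """One row per fish; absent phenotypes become NaN."""
    return pd.DataFrame([{
        "fish_id": s.fish_id, "population": s.population, "ecotype": s.ecotype,
        "fh20": s.fh20, "fh_peak": s.fh_peak, "t_ab": s.t_ab,
        "t_peak": s.t_peak, "q10": s.q10, "peak_cause": s.peak_cause,
    } for s in summaries])


def write_summaries(summaries: Sequence[CardiacSummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False)
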