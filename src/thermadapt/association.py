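"""Genotype–phenotype and genotype–environment association.

The phenotype-class window scan follows the within-ecotype design: fish of
one ecotype are ranked per population on a cardiac trait and split evenly
into low and high classes; loci with a genotyping success rate of at least
75% within the ecotype are kept; each marker is scored by a two-sided
Fisher exact test on the low/high x ref/alt allele table together with a
two-group Weir–Cockerham F_ST; marker p-values are combined over 10 kb
windows stepped every 200 bp with Stouffer's weighted z-score (weights =
sqrt of the called sample size), and window significance is controlled by
Benjamini–Yekutieli FDR.  A Lindley local-score segmentation is available
as an alternative aggregation that respects physical linkage.

Environment associations: per-locus ordinary least squares of minor allele
frequency on mean summer stream temperature, Mantel tests for isolation by
distance/temperature, and structure PCA with mean imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .genotypes import MISSING, GenotypeMatrix
from .scan import by_fdr, wc_fst_components
from .simulate import TemperatureSeries

log = logging.getLogger(__name__)

WINDOW_BP = 10_000
STEP_BP = 200

# z-transform clamps: Fisher p can be exactly 1 on monomorphic markers
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


# ------------------------------------------------------- thermal regimes

@dataclass
class RegimeSummary:
    """Thermal-regime summary of one stream's logger series."""

    stream_id: str
    daily_mean: float          # mean of daily mean temperatures, °C
    daily_max: float           # mean of daily maximum temperatures, °C
    mean_summer_temp: float    # mean over the summer window, °C
    max_summer_temp: float     # hottest reading in the summer window, °C
    max_diurnal_range: float   # largest single-day (max - min), °C


def summarize_regime(
    series: TemperatureSeries,
    summer_window: tuple[str, str] = ("2015-07-01", "2015-08-31"),
) -> RegimeSummary:
    """Daily aggregation, then window aggregation of a logger series."""
    df = series.to_frame().set_index("timestamp")
    daily = df["temp_c"].resample("1D").agg(["mean", "max", "min"]).dropna()
    lo, hi = pd.Timestamp(summer_window[0]), pd.Timestamp(summer_window[1])
    summer = df.loc[lo: hi + pd.Timedelta(days=1) - pd.Timedelta(seconds=1), "temp_c"]
    if summer.empty:
        raise ValueError("series does not cover the summer window")
    return RegimeSummary(
        stream_id=series.stream_id,
        daily_mean=float(daily["mean"].mean()),
        daily_max=float(daily["max"].mean()),
        mean_summer_temp=float(summer.mean()),
        max_summer_temp=float(summer.max()),
        max_diurnal_range=float((daily["max"] - daily["min"]).max()),
    )


# ------------------------------------------------------- phenotype classes

def split_phenotype_classes(
    summaries: pd.DataFrame, trait: str
) -> pd.DataFrame:
    """Rank fish on ``trait`` within each population and split evenly.

    The lower half is labelled ``low``, the upper half ``high``; with an
    odd count the median-ranked fish goes to ``low``.  Ties in trait
    values break deterministically by fish_id.  Fish with a missing trait
    are excluded; a population with the trait absent for every fish is an
    error.

    ``summaries`` needs columns fish_id, population, ecotype and the trait.
    Returns one row per labelled fish with a ``phen_class`` column.
    """
    if trait not in summaries.columns:
        raise ValueError(f"unknown trait {trait!r}")
    out = []
    for pop, grp in summaries.groupby("population", sort=False):
        defined = grp.dropna(subset=[trait])
        if defined.empty:
            raise ValueError(f"trait {trait!r} absent for population {pop!r}")
        if len(defined) < 2:
            raise ValueError(f"population {pop!r} has <2 fish with {trait!r}")
        ranked = defined.sort_values([trait, "fish_id"], kind="stable")
        n = len(ranked)
        n_low = (n + 1) // 2
        labels = np.array(["low"] * n_low + ["high"] * (n - n_low))
        sub = ranked[["fish_id", "population", "ecotype", trait]].copy()
        sub["phen_class"] = labels
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    sizes = result.groupby(["population", "phen_class"]).size().unstack(fill_value=0)
    assert (abs(sizes.get("low", 0) - sizes.get("high", 0)) <= 1).all()
    return result


def class_coverage_filter(
    g: GenotypeMatrix, fish_index: np.ndarray, min_rate: float = 0.75
) -> np.ndarray:
    """Boolean mask of loci with a genotyping success rate of at least
    ``min_rate`` among the given fish (row indices)."""
    fish_index = np.asarray(fish_index)
    if len(fish_index) == 0:
        raise ValueError("empty fish set")
    called = g.calls[fish_index, :] != MISSING
    return called.mean(axis=0) >= min_rate


# ------------------------------------------------------- marker tests

def fisher_exact_2x2(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p for a stack of 2x2 tables (L, 2, 2).

    Vectorised hypergeometric enumeration: for each table, the two-sided p
    sums the probabilities of all outcomes no more likely than the one
    observed (scipy's convention, with the same 1+1e-7 likelihood slack).
    """
    t = np.asarray(tables, dtype=np.int64)
    if t.ndim == 2:
        t = t[None]
    k = t[:, 0, 0]
    n1 = t[:, 0, 0] + t[:, 0, 1]            # row-1 total (draws)
    K = t[:, 0, 0] + t[:, 1, 0]             # column-1 total (successes)
    N = t.sum(axis=(1, 2))

    x_max = int(np.minimum(n1, K).max(initial=0))
    x = np.arange(x_max + 1)[None, :]       # candidate counts
    lo = np.maximum(0, n1 + K - N)[:, None]
    hi = np.minimum(n1, K)[:, None]
    valid = (x >= lo) & (x <= hi)

    def log_comb(a, b):
        return special.gammaln(a + 1) - special.gammaln(b + 1) \
            - special.gammaln(a - b + 1)

    with np.errstate(invalid="ignore"):
        logpmf = (log_comb(K[:, None], x) + log_comb((N - K)[:, None], n1[:, None] - x)
                  - log_comb(N[:, None], n1[:, None]))
    logpmf = np.where(valid, logpmf, -np.inf)
    log_obs = np.take_along_axis(logpmf, k[:, None], axis=1)
    include = logpmf <= log_obs + np.log(1 + 1e-7)
    p = np.exp(logpmf, where=np.isfinite(logpmf), out=np.zeros_like(logpmf))
    pval = np.where(include & valid, p, 0.0).sum(axis=1)
    pval = np.clip(pval, 0.0, 1.0)
    # degenerate margins (empty row or column) carry no information
    pval[(n1 == 0) | (K == 0) | (K == N) | (n1 == N)] = 1.0
    return pval


def marker_class_tests(
    g: GenotypeMatrix, labels: pd.DataFrame
) -> pd.DataFrame:
    """Per-marker two-group F_ST and Fisher exact p between phenotype classes.

    ``labels`` is the output of :func:`split_phenotype_classes` restricted
    to the fish present in ``g``.  Allele counts come from genotype codes
    (het contributes one allele of each kind).  Returns one row per locus
    with ``fst, fisher_p, n_called, weight`` plus locus coordinates.
    """
    ids = g.individuals["individual_id"]
    id_to_row = {fid: i for i, fid in enumerate(ids)}
    low_ids = labels.loc[labels["phen_class"] == "low", "fish_id"]
    high_ids = labels.loc[labels["phen_class"] == "high", "fish_id"]
    low_idx = np.array([id_to_row[f] for f in low_ids if f in id_to_row])
    high_idx = np.array([id_to_row[f] for f in high_ids if f in id_to_row])
    if len(low_idx) == 0 or len(high_idx) == 0:
        raise ValueError("a phenotype class has no genotyped fish")

    def counts(idx):
        sub = g.calls[idx, :]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        return alt, tot, called.sum(axis=0)

    alt_lo, tot_lo, n_lo = counts(low_idx)
    alt_hi, tot_hi, n_hi = counts(high_idx)

    tables = np.stack([
        np.stack([alt_lo, tot_lo - alt_lo], axis=1),
        np.stack([alt_hi, tot_hi - alt_hi], axis=1),
    ], axis=1)                                  # (L, 2, 2): class x allele
    fisher_p = fisher_exact_2x2(tables)

    a, b, c = wc_fst_components(g.calls, [low_idx, high_idx])
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(np.abs(a + b + c) > 0, a / (a + b + c), np.nan)

    n_called = n_lo + n_hi
    return pd.DataFrame({
        "locus_id": g.loci["locus_id"],
        "chrom": g.loci["chrom"],
        "pos_bp": g.loci["pos_bp"],
        "fst": fst,
        "comp_a": a,
        "comp_abc": a + b + c,
        "fisher_p": fisher_p,
        "n_called": n_called,
        "weight": np.sqrt(n_called),
    })


# ------------------------------------------------------- window scan

def window_scan(
    markers: pd.DataFrame,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Sliding-window combination of marker evidence along the genome.

    Windows are ``window`` bp wide (0-based half-open), step-anchored at
    position 0 of each chromosome every ``step`` bp; windows without
    markers are not emitted.  Per window: F_ST is the ratio of summed
    Weir–Cockerham components over member markers, and the combined
    p-value is Stouffer's weighted z, ``Z = sum(w z) / sqrt(sum(w^2))``
    with ``z_i = Phi^{-1}(1 - p_i)``.  BY-FDR at ``fdr_level`` over all
    emitted windows sets the significance flag.

    ``markers`` must be sorted by (chrom, pos_bp); required columns:
    chrom, pos_bp, fisher_p, weight, comp_a, comp_abc.
    """
    required = {"chrom", "pos_bp", "fisher_p", "weight", "comp_a", "comp_abc"}
    if not required <= set(markers.columns):
        raise ValueError(f"markers table missing {sorted(required - set(markers.columns))}")
    pos_sorted = markers.sort_values(["chrom", "pos_bp"], kind="stable")
    if not pos_sorted[["chrom", "pos_bp"]].reset_index(drop=True).equals(
        markers[["chrom", "pos_bp"]].reset_index(drop=True)
    ):
        raise ValueError("markers must be sorted by (chrom, pos_bp)")

    frames = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        p = np.clip(grp["fisher_p"].to_numpy(dtype=float), _P_FLOOR, _P_CEIL)
        w = grp["weight"].to_numpy(dtype=float)
        z = stats.norm.isf(p)
        comp_a = np.nan_to_num(grp["comp_a"].to_numpy(dtype=float))
        comp_abc = np.nan_to_num(grp["comp_abc"].to_numpy(dtype=float))

        first = max(0, (int(pos.min()) - window) // step + 1) * step
        # ensure anchoring: first multiple of step whose window reaches min pos
        starts = np.arange(first, int(pos.max()) + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        nonempty = hi > lo
        starts, lo, hi = starts[nonempty], lo[nonempty], hi[nonempty]

        cw_z = np.concatenate(([0.0], np.cumsum(w * z)))
        cw_2 = np.concatenate(([0.0], np.cumsum(w ** 2)))
        c_a = np.concatenate(([0.0], np.cumsum(comp_a)))
        c_abc = np.concatenate(([0.0], np.cumsum(comp_abc)))

        zsum = cw_z[hi] - cw_z[lo]
        w2 = cw_2[hi] - cw_2[lo]
        Z = zsum / np.sqrt(w2)
        a_sum = c_a[hi] - c_a[lo]
        abc_sum = c_abc[hi] - c_abc[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            wfst = np.where(np.abs(abc_sum) > 0, a_sum / abc_sum, np.nan)

        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "n_markers": hi - lo,
            "window_fst": wfst,
            "combined_p": np.clip(stats.norm.sf(Z), _P_FLOOR, 1.0),
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_markers",
                                     "window_fst", "combined_p", "significant"])
    out = pd.concat(frames, ignore_index=True)
    rejected, _ = by_fdr(out["combined_p"].to_numpy(), fdr_level)
    out["significant"] = rejected
    return out


def local_score_segments(
    p: np.ndarray, xi: float = 2.0
) -> pd.DataFrame:
    """Lindley local-score segmentation of ordered marker p-values.

    Scores ``h_i = -log10(p_i) - xi`` accumulate through the recursion
    ``L_i = max(0, L_{i-1} + h_i)``; maximal runs with ``L > 0`` become
    segments scored by their peak ``L``.  Marker order must follow genome
    position on one chromosome.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    p = np.clip(np.asarray(p, dtype=float), _P_FLOOR, 1.0)
    h = -np.log10(p) - xi
    segments = []
    lindley = 0.0
    start = None
    best = 0.0
    best_idx = None
    for i, hi_ in enumerate(h):
        lindley = max(0.0, lindley + hi_)
        if lindley > 0 and start is None:
            start, best, best_idx = i, lindley, i
        elif lindley > 0 and lindley > best:
            best, best_idx = lindley, i
        elif lindley == 0 and start is not None:
            segments.append((start, i - 1, best, best_idx))
            start, best, best_idx = None, 0.0, None
    if start is not None:
        segments.append((start, len(h) - 1, best, best_idx))
    return pd.DataFrame(segments,
                        columns=["start_idx", "end_idx", "score", "peak_idx"])


# ------------------------------------------------------- environment

def minor_allele_frequencies(g: GenotypeMatrix) -> pd.DataFrame:
    """Loci x populations table of the metapopulation minor allele's
    frequency in each population.

    The minor allele is defined once from the pooled sample so that a
    clinal locus keeps a monotone frequency profile across populations
    (folding per population would destroy the cline).
    """
    from .genotypes import allele_frequencies

    pops = g.pop_indices()
    global_p = allele_frequencies(g.calls)
    flip = global_p > 0.5
    cols = {}
    for pop, idx in pops.items():
        p = allele_frequencies(g.calls[idx, :])
        cols[pop] = np.where(flip, 1 - p, p)
    return pd.DataFrame(cols, index=g.loci["locus_id"])


def maf_temperature_association(
    maf: pd.DataFrame, pop_temps: pd.Series, top_n: int = 20
) -> pd.DataFrame:
    """Rank loci by the strength of the MAF ~ temperature regression.

    ``maf`` is loci x populations (minor allele frequency), ``pop_temps``
    mean summer temperature per population (same column labels).
    Ordinary least squares per locus; loci ranked by ascending p with ties
    broken by descending absolute slope; the ``top_n`` strongest are
    returned with slope, r² and p.
    """
    temps = pop_temps.reindex(maf.columns).to_numpy(dtype=float)
    if len(temps) < 3:
        raise ValueError("need at least 3 populations")
    if np.ptp(temps) == 0:
        raise ValueError("temperature vector is constant")
    Y = maf.to_numpy(dtype=float)
    x = temps - temps.mean()
    sxx = float((x ** 2).sum())
    ybar = Y.mean(axis=1)
    sxy = (Y * x).sum(axis=1)
    slope = sxy / sxx
    syy = ((Y - ybar[:, None]) ** 2).sum(axis=1)
    n = len(temps)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, (sxy ** 2) / (sxx * syy), 0.0)
        tstat = np.sqrt(np.maximum(r2, 0) * (n - 2) / np.maximum(1 - r2, 1e-300))
    pval = 2 * stats.t.sf(np.abs(tstat), n - 2)
    out = pd.DataFrame({
        "locus_id": maf.index,
        "slope": slope,
        "r2": r2,
        "p": pval,
        "abs_slope": np.abs(slope),
    }).sort_values(["p", "abs_slope"], ascending=[True, False],
                   kind="stable").drop(columns="abs_slope")
    return out.head(min(top_n, len(out))).reset_index(drop=True)


def mantel(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of distance matrices with a
    label-permutation p-value.

    Matrices must be symmetric with zero diagonals and matching shape.
    ``alternative`` is ``greater`` (default, the isolation-by-distance
    convention), ``less`` or ``two-sided``.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and matching")
    for m in (a, b):
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal must be zero")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(m1, m2):
        v1, v2 = m1[iu], m2[iu]
        v1 = v1 - v1.mean()
        v2 = v2 - v2.mean()
        denom = np.sqrt((v1 ** 2).sum() * (v2 ** 2).sum())
        return float(v1 @ v2 / denom) if denom > 0 else 0.0

    r_obs = corr(a, b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(a, b[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "less":
            count += r_p <= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    return r_obs, (count + 1) / (n_perm + 1)


def read_distance_matrix(path) -> pd.DataFrame:
    """Labeled symmetric distance matrix from a tab-separated file (row
    and column labels must match; diagonal zero)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels differ")
    m = df.to_numpy(dtype=float)
    if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
        raise ValueError("matrix must be symmetric with a zero diagonal")
    return df


def pairwise_linearized_fst(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise F_ST / (1 - F_ST) between populations (mean-of-ratio over
    the multi-locus ratio-of-sums estimate); the genetic distance used for
    isolation-by-distance Mantel tests."""
    pops = g.pop_indices()
    names = list(pops)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, pa in enumerate(names):
        for pb in names[i + 1:]:
            a, b_, c = wc_fst_components(g.calls, [pops[pa], pops[pb]])
            ok = np.isfinite(a) & np.isfinite(b_) & np.isfinite(c)
            theta = float(a[ok].sum() / (a[ok] + b_[ok] + c[ok]).sum())
            theta = min(theta, 0.999)
            val = max(theta, 0.0) / (1 - max(theta, 0.0))
            out.loc[pa, pb] = out.loc[pb, pa] = val
    return out


def structure_pca(
    g: GenotypeMatrix,
    loci_subset: Optional[np.ndarray] = None,
    n_components: Optional[int] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of individuals on mean-imputed, centred genotype codes.

    Missing calls are replaced by the locus mean before centring; the
    eigendecomposition orders components by decreasing explained variance
    and fixes signs so each component's largest-magnitude loading is
    positive.  Returns ``(coordinates, explained_variance_ratio)``.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    sub = g if loci_subset is None else g.subset_loci(loci_subset)
    X = sub.calls.astype(float)
    X[X == MISSING] = np.nan
    has_calls = ~np.isnan(X).all(axis=0)
    col_mean = np.zeros(X.shape[1])
    col_mean[has_calls] = np.nanmean(X[:, has_calls], axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X) - col_mean[None, :]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components or min(10, len(S))
    # sign convention: largest-|loading| entry of each component positive
    for comp in range(min(k, Vt.shape[0])):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    var = S ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    coords = pd.DataFrame(
        U[:, :k] * S[:k],
        index=sub.individuals["individual_id"],
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    coords["population"] = sub.individuals["population"].to_numpy()
    coords["ecotype"] = sub.individuals["ecotype"].to_numpy()
    return coords, ratio[:k]
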