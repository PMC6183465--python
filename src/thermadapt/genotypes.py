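"""Genotype containers, I/O and catalog filtering for RAD-seq SNP panels.

Genotypes are biallelic, coded 0/1/2 as the count of the alternate allele
with ``-1`` marking a missing call.  Loci carry RAD-tag, chromosome and
position metadata; individuals carry population and ecotype labels.

The catalog filter reproduces the four-step cleaning applied to de-novo
RAD catalogs: (a) drop every SNP on a tag carrying more than four SNPs
(putative paralogs / hypervariable tags), (b) drop SNPs with more than two
alleles, (c) drop SNPs missing more than 25% of genotypes across all
populations, and (d) drop SNPs whose minor allele frequency falls below
0.02 in any single population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

LOCUS_COLUMNS = ["locus_id", "tag_id", "chrom", "pos_bp", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci with metadata.

    ``calls`` is an ``(n_individuals, n_loci)`` int8/int16 array in
    {0, 1, 2, -1}.  ``individuals`` is a DataFrame with columns
    ``individual_id, population, ecotype``; ``loci`` a DataFrame with
    :data:`LOCUS_COLUMNS`.
    """

    calls: np.ndarray
    individuals: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x loci)")
        if len(self.individuals) != self.calls.shape[0]:
            raise ValueError("individuals table does not match calls rows")
        if len(self.loci) != self.calls.shape[1]:
            raise ValueError("loci table does not match calls columns")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if (self.loci["pos_bp"] < 0).any():
            raise ValueError("locus positions must be non-negative")
        self.individuals = self.individuals.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.individuals["population"]))

    def pop_indices(self) -> dict[str, np.ndarray]:
        pops = self.individuals["population"].to_numpy()
        return {p: np.flatnonzero(pops == p) for p in self.populations}

    def subset_loci(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            calls=self.calls[:, idx],
            individuals=self.individuals.copy(),
            loci=self.loci.iloc[idx].reset_index(drop=True),
        )

    def subset_individuals(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            calls=self.calls[idx, :],
            individuals=self.individuals.iloc[idx].reset_index(drop=True),
            loci=self.loci.copy(),
        )


# ---------------------------------------------------------------- I/O

def read_pop_map(path) -> pd.DataFrame:
    """Two-column whitespace table: individual_id, population[, ecotype]."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        df.columns = ["individual_id", "population"]
        df["ecotype"] = df["population"]
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
        df.columns = ["individual_id", "population", "ecotype"]
    else:
        raise ValueError("population map needs at least two columns")
    return df


def write_pop_map(individuals: pd.DataFrame, path) -> None:
    individuals[["individual_id", "population", "ecotype"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes (missing as ./.)."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=TAG,Number=1,Type=String,Description="RAD tag">\n')
        for chrom in dict.fromkeys(g.loci["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = "\t".join(g.individuals["individual_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        loci = g.loci
        for j in range(g.n_loci):
            row = loci.iloc[j]
            gts = "\t".join(code_to_gt[int(c)] for c in g.calls[:, j])
            # VCF POS is 1-based
            fh.write(
                f"{row.chrom}\t{int(row.pos_bp) + 1}\t{row.locus_id}\t"
                f"{row.ref}\t{row.alt}\t.\t.\tTAG={row.tag_id}\tGT\t{gts}\n"
            )


def _read_vcf(path, pop_map: pd.DataFrame) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls_cols: list[np.ndarray] = []
    loci_rows = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        calls_cols.append(col)
        tag = ""
        try:
            tag = str(var.INFO.get("TAG") or "")
        except Exception:
            pass
        loci_rows.append((
            var.ID or f"{var.CHROM}:{var.POS}", tag, str(var.CHROM),
            var.POS - 1, var.REF, var.ALT[0],
        ))
    if n_multiallelic:
        log.info("excluded %d multi-allelic VCF records", n_multiallelic)
    calls = (np.stack(calls_cols, axis=1) if calls_cols
             else np.empty((len(samples), 0), dtype=np.int8))
    loci = pd.DataFrame(loci_rows, columns=LOCUS_COLUMNS)
    individuals = pd.DataFrame({"individual_id": samples}).merge(
        pop_map, on="individual_id", how="left"
    )
    return calls, individuals, loci


def write_tab_matrix(g: GenotypeMatrix, path) -> None:
    """Plain tab-separated matrix: locus metadata columns then one column
    per individual; missing written as ``NA``."""
    codes = g.calls.T.astype(object)
    codes[codes == MISSING] = "NA"
    body = pd.DataFrame(codes, columns=list(g.individuals["individual_id"]))
    pd.concat([g.loci.reset_index(drop=True), body], axis=1).to_csv(
        path, sep="\t", index=False)


def _read_tab_matrix(path, pop_map: pd.DataFrame):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[LOCUS_COLUMNS]
    sample_cols = [c for c in df.columns if c not in LOCUS_COLUMNS]
    raw = df[sample_cols].to_numpy(dtype=object).T
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    numeric = pd.DataFrame(raw).apply(pd.to_numeric, errors="coerce").to_numpy()
    ok = ~np.isnan(numeric)
    calls[ok] = numeric[ok].astype(np.int8)
    individuals = pd.DataFrame({"individual_id": sample_cols}).merge(
        pop_map, on="individual_id", how="left"
    )
    return calls, individuals, meta


def read_genotypes(path, pop_map_path) -> GenotypeMatrix:
    """Read genotypes from VCF (``.vcf``) or the tab-matrix format, joining
    population/ecotype labels from a population map file.

    Raises on individuals absent from the population map; multi-allelic
    VCF records are excluded with a logged count.
    """
    pop_map = read_pop_map(pop_map_path)
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        calls, individuals, loci = _read_vcf(path, pop_map)
    else:
        calls, individuals, loci = _read_tab_matrix(path, pop_map)
    if individuals["population"].isna().any():
        missing = individuals.loc[
            individuals["population"].isna(), "individual_id"
        ].tolist()
        raise ValueError(f"individuals absent from population map: {missing}")
    return GenotypeMatrix(calls=calls, individuals=individuals, loci=loci)


# ---------------------------------------------------------------- filters

@dataclass
class FilterReport:
    """Per-rule exclusion counts for the catalog filter."""

    n_input: int
    removed_tag_snp_count: int      # rule (a): tag with > max_snps_per_tag SNPs
    removed_multiallelic: int       # rule (b)
    removed_missingness: int        # rule (c): missing fraction > threshold
    removed_low_maf: int            # rule (d): MAF < threshold in any population
    n_surviving: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rule": ["input", "(a) tag_snp_count", "(b) multiallelic",
                     "(c) missingness", "(d) low_maf", "surviving"],
            "count": [self.n_input, self.removed_tag_snp_count,
                      self.removed_multiallelic, self.removed_missingness,
                      self.removed_low_maf, self.n_surviving],
        })

    def __str__(self) -> str:
        f = self.to_frame()
        return "\n".join(f"{r.rule}: {r.count}" for r in f.itertuples())


def filter_catalog(
    g: GenotypeMatrix,
    max_snps_per_tag: int = 4,
    max_missing_frac: float = 0.25,
    min_pop_maf: float = 0.02,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the four catalog-cleaning rules in order.

    Thresholds are strict as worded: a tag is dropped when it has *more
    than* ``max_snps_per_tag`` SNPs, a locus when *more than*
    ``max_missing_frac`` of genotypes are missing, or when its minor allele
    frequency falls *below* ``min_pop_maf`` in any population.  Exclusion
    counts are attributed to the first rule that removes each locus.
    """
    keep = np.ones(g.n_loci, dtype=bool)

    # (a) tags with too many SNPs
    tag_counts = g.loci.groupby("tag_id")["locus_id"].transform("size").to_numpy()
    rule_a = tag_counts > max_snps_per_tag
    n_a = int(rule_a.sum())
    keep &= ~rule_a

    # (b) multi-allelic loci: the in-memory code space is biallelic, so this
    # only catches loci flagged upstream (e.g. 'n_alleles' metadata column)
    if "n_alleles" in g.loci.columns:
        rule_b = (g.loci["n_alleles"].to_numpy() > 2) & keep
    else:
        rule_b = np.zeros(g.n_loci, dtype=bool)
    n_b = int(rule_b.sum())
    keep &= ~rule_b

    # (c) missingness across all populations jointly
    missing_frac = (g.calls == MISSING).mean(axis=0)
    rule_c = (missing_frac > max_missing_frac) & keep
    n_c = int(rule_c.sum())
    keep &= ~rule_c

    # (d) per-population minor allele frequency
    rule_d = np.zeros(g.n_loci, dtype=bool)
    for pop, idx in g.pop_indices().items():
        calls = g.calls[idx, :]
        called = calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0,
                         np.where(called, calls, 0).sum(axis=0) / n_alleles, np.nan)
        maf = np.minimum(p, 1 - p)
        rule_d |= np.nan_to_num(maf, nan=0.0) < min_pop_maf
    rule_d &= keep
    n_d = int(rule_d.sum())
    keep &= ~rule_d

    report = FilterReport(
        n_input=g.n_loci,
        removed_tag_snp_count=n_a,
        removed_multiallelic=n_b,
        removed_missingness=n_c,
        removed_low_maf=n_d,
        n_surviving=int(keep.sum()),
    )
    assert report.n_surviving + n_a + n_b + n_c + n_d == report.n_input
    return g.subset_loci(keep), report


# ---------------------------------------------------------------- stats

def allele_frequencies(calls: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per locus from coded calls (NaN if uncalled)."""
    called = calls != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def locus_stats(g: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population, per-locus allele frequency and heterozygosity.

    Observed heterozygosity Ho is the fraction of heterozygous calls;
    expected heterozygosity uses the small-sample unbiased estimator
    ``He = 2 p (1 - p) * 2n / (2n - 1)`` with ``p`` from called alleles.
    Returns ``(per_locus, per_population_means)``; means are taken over
    loci with defined values.
    """
    rows = []
    for pop, idx in g.pop_indices().items():
        calls = g.calls[idx, :]
        called = calls != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0,
                         np.where(called, calls, 0).sum(axis=0) / (2 * n_called),
                         np.nan)
            ho = np.where(n_called > 0,
                          (calls == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
            two_n = 2 * n_called
            he = np.where(two_n > 1,
                          2 * p * (1 - p) * two_n / np.maximum(two_n - 1, 1), np.nan)
        rows.append(pd.DataFrame({
            "locus_id": g.loci["locus_id"],
            "population": pop,
            "alt_freq": p,
            "maf": np.minimum(p, 1 - p),
            "ho": ho,
            "he": he,
            "genotyping_rate": n_called / len(idx),
        }))
    per_locus = pd.concat(rows, ignore_index=True)
    means = (per_locus.groupby("population", sort=False)[
        ["ho", "he", "genotyping_rate"]].mean().reset_index())
    return per_locus, means
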