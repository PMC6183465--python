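"""End-to-end orchestration: simulate -> cardiac -> qc -> scan -> assoc -> annotate.

A single YAML config drives the run; every stage writes tab-separated
tables into the run directory, stamped with the config hash and seed so a
rerun with the same config reproduces the outputs.  Gene proximity
annotation retrieves coding sequence within a 5 kb flank of outlier SNPs
and genes overlapping significant windows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import association, cardiac, genotypes, scan, simulate

log = logging.getLogger(__name__)

SNP_FLANK_BP = 5_000


# ------------------------------------------------------- gene intervals

def read_bed(path) -> pd.DataFrame:
    """BED intervals (already 0-based half-open): chrom, start, end
    [, name, score, strand]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    cols = ["chrom", "start", "end", "gene_name", "score", "strand"]
    df.columns = cols[: df.shape[1]]
    if "gene_name" not in df.columns:
        df["gene_name"] = [f"feature{i}" for i in range(len(df))]
    if "strand" not in df.columns:
        df["strand"] = "."
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError("BED intervals must satisfy start < end")
    return df[["chrom", "start", "end", "strand", "gene_name"]]


def read_gff3(path, feature_types=("gene", "CDS")) -> pd.DataFrame:
    """GFF3 intervals normalised to 0-based half-open coordinates."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"chrom": str},
    )
    df = df[df["type"].isin(feature_types)].copy()

    def name_of(attrs: str) -> str:
        for key in ("Name=", "gene=", "ID="):
            for part in str(attrs).split(";"):
                if part.startswith(key):
                    return part[len(key):]
        return "unnamed"

    df["gene_name"] = df["attributes"].map(name_of)
    df["start"] = df["start"].astype(int) - 1     # 1-based closed -> 0-based half-open
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise ValueError("malformed GFF interval (start >= end after conversion)")
    return df[["chrom", "start", "end", "strand", "gene_name"]].reset_index(drop=True)


def read_gene_intervals(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return read_gff3(path)
    return read_bed(path)


def proximity_annotate(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = SNP_FLANK_BP,
    windows: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Gene proximity annotation.

    SNP mode: a gene is linked to a SNP when its interval comes within
    ``flank`` bp of the SNP position (a gene ending exactly ``flank`` bp
    away is included).  Window mode (when ``windows`` is given): genes
    overlapping the window interval by at least 1 bp, no flank.  Gene
    lists are sorted and deterministic; chromosome names present in the
    query but absent from the gene set are reported, not fatal.

    ``snps`` needs columns locus_id, chrom, pos_bp; ``windows`` chrom,
    start, end.  Returns ``(snp_genes, window_genes)`` with comma-joined
    gene lists.
    """
    missing_chroms = set(snps["chrom"]) - set(genes["chrom"])
    if missing_chroms:
        log.warning("no gene annotations for chromosomes: %s",
                    sorted(missing_chroms))

    by_chrom = {c: sub.sort_values("start") for c, sub in genes.groupby("chrom")}

    def genes_near(chrom, lo, hi):
        sub = by_chrom.get(chrom)
        if sub is None:
            return []
        hit = (sub["start"] < hi) & (sub["end"] > lo)
        return sorted(set(sub.loc[hit, "gene_name"]))

    snp_rows = []
    for row in snps.itertuples():
        # distance-<=-flank means the gene interval intersects
        # [pos - flank, pos + flank + 1) around the SNP base
        hits = genes_near(row.chrom, row.pos_bp - flank, row.pos_bp + flank + 1)
        snp_rows.append((row.locus_id, row.chrom, row.pos_bp, ",".join(hits)))
    snp_genes = pd.DataFrame(snp_rows,
                             columns=["locus_id", "chrom", "pos_bp", "genes"])

    window_genes = None
    if windows is not None:
        win_rows = []
        for row in windows.itertuples():
            hits = genes_near(row.chrom, row.start, row.end)
            win_rows.append((row.chrom, row.start, row.end, ",".join(hits)))
        window_genes = pd.DataFrame(win_rows,
                                    columns=["chrom", "start", "end", "genes"])
    return snp_genes, window_genes


# ------------------------------------------------------- configuration

@dataclass
class RunConfig:
    """Schema-validated configuration for :func:`run_pipeline`."""

    seed: int = 1
    out_dir: str = "runs/default"
    # stage toggles
    run_simulate: bool = True
    run_cardiac: bool = True
    run_qc: bool = True
    run_scan: bool = True
    run_assoc: bool = True
    run_annotate: bool = True
    run_bayes: bool = False
    # simulation scale
    n_pops: int = 6
    n_per_pop: int = 20
    n_loci: int = 20_000
    n_causal: int = 50
    cline_slope: float = simulate.DEFAULT_CLINE_SLOPE
    neutral_fst_target: float = 0.05
    missing_rate: float = 0.05
    trial_noise_bpm: float = 2.0
    # filters and thresholds
    max_snps_per_tag: int = 4
    max_missing_frac: float = 0.25
    min_pop_maf: float = 0.02
    pca_k: int = 3
    fdr_level: float = 0.05
    min_methods: int = 2
    bayes_bf_threshold: float = 3.0
    bayes_fdr: float = 0.1
    window_bp: int = association.WINDOW_BP
    step_bp: int = association.STEP_BP
    use_local_score: bool = False     # Lindley segmentation alongside windows
    local_score_xi: float = 2.0
    class_min_rate: float = 0.75
    assoc_trait: str = "fh20"
    top_n_temperature: int = 20
    # MCMC lengths (desk-scale defaults)
    bayes_pilot_runs: int = 2
    bayes_pilot_len: int = 1000
    bayes_burn_in: int = 5000
    bayes_iterations: int = 5000
    # optional external inputs
    genotypes_path: Optional[str] = None
    pop_map_path: Optional[str] = None
    trials_path: Optional[str] = None
    genes_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory; every table is tab-separated and carries
    the config hash and seed in ``run_info.json``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    info = {"config_hash": config.config_hash(), "seed": config.seed,
            "stages": []}
    report_lines = [f"run {config.config_hash()} seed {config.seed}"]

    g = truth = None
    if config.run_simulate:
        truth = simulate.default_truth(
            n_loci=config.n_loci, n_causal=config.n_causal,
            cline_slope=config.cline_slope,
            neutral_fst_target=config.neutral_fst_target, seed=config.seed,
        )
        g, truth = simulate.simulate_island_genotypes(
            n_pops=config.n_pops, n_per_pop=config.n_per_pop,
            n_loci=config.n_loci, truth=truth,
            missing_rate=config.missing_rate,
        )
        genotypes.write_tab_matrix(g, out / "genotypes.tsv")
        genotypes.write_pop_map(g.individuals, out / "pop_map.tsv")
        truth.save(out / "truth.tsv")
        trials = simulate.simulate_cohort_trials(
            g, truth, noise_sd=config.trial_noise_bpm)
        cardiac.write_trials(trials, out / "trials.tsv")
        info["stages"].append("simulate")
    else:
        if not (config.genotypes_path and config.pop_map_path):
            raise ValueError("need genotypes_path and pop_map_path when the "
                             "simulate stage is disabled")
        g = genotypes.read_genotypes(config.genotypes_path, config.pop_map_path)
        trials = (cardiac.read_trials(config.trials_path)
                  if config.trials_path else [])

    summaries = None
    if config.run_cardiac and trials:
        summaries = [cardiac.summarize_trial(t) for t in trials]
        cardiac.write_summaries(summaries, out / "cardiac_summaries.tsv")
        frame = cardiac.summaries_to_frame(summaries)
        by_pop = frame.groupby("population")[
            ["fh20", "fh_peak", "t_ab", "t_peak", "q10"]].agg(["mean", "sem"])
        by_pop.to_csv(out / "cardiac_population_means.tsv", sep="\t")
        info["stages"].append("cardiac")
        report_lines.append(f"cardiac: {len(summaries)} fish summarised")

    if config.run_qc:
        g, report = genotypes.filter_catalog(
            g, config.max_snps_per_tag, config.max_missing_frac,
            config.min_pop_maf)
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        per_locus, pop_means = genotypes.locus_stats(g)
        pop_means.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
        info["stages"].append("qc")
        report_lines.append(f"qc: {report.n_surviving}/{report.n_input} loci kept")

    scan_result = None
    if config.run_scan:
        bayes_cfg = scan.BayesScanConfig(
            pilot_runs=config.bayes_pilot_runs, pilot_len=config.bayes_pilot_len,
            burn_in=config.bayes_burn_in, iterations=config.bayes_iterations,
            seed=config.seed,
        )
        scan_result = scan.scan_outliers(
            g, k=config.pca_k, fdr_level=config.fdr_level,
            min_methods=config.min_methods, run_bayes=config.run_bayes,
            bayes_config=bayes_cfg, bayes_bf_threshold=config.bayes_bf_threshold,
            bayes_fdr=config.bayes_fdr,
        )
        scan_result.table.to_csv(out / "outlier_scan.tsv", sep="\t", index=False)
        cons = scan_result.table[scan_result.table["consensus"]]
        bed = pd.DataFrame({
            "chrom": cons["chrom"], "start": cons["pos_bp"],
            "end": cons["pos_bp"] + 1, "name": cons["locus_id"],
        })
        bed.to_csv(out / "consensus_outliers.bed", sep="\t", index=False,
                   header=False)
        info["stages"].append("scan")
        report_lines.append(
            f"scan: {int(cons.shape[0])} consensus outliers "
            f"(lambda trimmed {scan_result.lambda_trimmed:.3f}, "
            f"pca {scan_result.lambda_pca:.3f})")
        if truth is not None:
            causal = set(truth.causal_locus_ids)
            called = set(cons["locus_id"])
            present = causal & set(scan_result.table["locus_id"])
            sens = len(called & causal) / max(len(present), 1)
            neutral = set(scan_result.table["locus_id"]) - causal
            fpr = len(called & neutral) / max(len(neutral), 1)
            report_lines.append(
                f"scan truth recovery: sensitivity {sens:.2f}, "
                f"neutral false-positive rate {fpr:.4f}")

    windows = None
    if config.run_assoc and summaries is not None:
        frame = cardiac.summaries_to_frame(summaries)
        window_frames = []
        for ecotype, eco_frame in frame.groupby("ecotype", sort=False):
            labels = association.split_phenotype_classes(
                eco_frame, config.assoc_trait)
            fish_idx = np.flatnonzero(
                g.individuals["ecotype"].to_numpy() == ecotype)
            keep = association.class_coverage_filter(
                g, fish_idx, config.class_min_rate)
            sub = g.subset_individuals(fish_idx).subset_loci(keep)
            markers = association.marker_class_tests(sub, labels)
            markers = markers.sort_values(["chrom", "pos_bp"], kind="stable")
            markers = markers.reset_index(drop=True)
            win = association.window_scan(
                markers, window=config.window_bp,
                step=config.step_bp, fdr_level=config.fdr_level)
            win.insert(0, "ecotype", ecotype)
            window_frames.append(win)
            if config.use_local_score:
                seg_frames = []
                for chrom, chrom_markers in markers.groupby("chrom", sort=False):
                    seg = association.local_score_segments(
                        chrom_markers["fisher_p"].to_numpy(),
                        xi=config.local_score_xi)
                    if len(seg):
                        pos = chrom_markers["pos_bp"].to_numpy()
                        seg.insert(0, "chrom", chrom)
                        seg["start_bp"] = pos[seg["start_idx"]]
                        seg["end_bp"] = pos[seg["end_idx"]]
                        seg_frames.append(seg)
                if seg_frames:
                    pd.concat(seg_frames, ignore_index=True).to_csv(
                        out / f"local_score_{ecotype}_{config.assoc_trait}.tsv",
                        sep="\t", index=False)
        windows = pd.concat(window_frames, ignore_index=True)
        windows.to_csv(out / f"windows_{config.assoc_trait}.tsv", sep="\t",
                       index=False)
        n_sig = int(windows["significant"].sum())
        report_lines.append(f"assoc[{config.assoc_trait}]: {n_sig} significant "
                            f"windows of {len(windows)}")

        if scan_result is not None:
            cons_ids = scan_result.table.loc[
                scan_result.table["consensus"], "locus_id"]
            maf = association.minor_allele_frequencies(g)
            maf = maf[maf.index.isin(cons_ids)]
            temps = pd.Series(simulate.DEFAULT_POP_TEMPS[: config.n_pops],
                              index=list(simulate.DEFAULT_POPS[: config.n_pops]))
            if len(maf) >= 1:
                top = association.maf_temperature_association(
                    maf.dropna(), temps, config.top_n_temperature)
                top.to_csv(out / "temperature_associated_loci.tsv", sep="\t",
                           index=False)
                report_lines.append(
                    f"assoc: {len(top)} temperature-associated outliers")
        info["stages"].append("assoc")

    if config.run_annotate and scan_result is not None:
        if config.genes_path:
            genes = read_gene_intervals(config.genes_path)
        else:
            genes = _synthetic_gene_set(config.seed)
        cons = scan_result.table[scan_result.table["consensus"]]
        sig_windows = (windows[windows["significant"]]
                       if windows is not None else None)
        snp_genes, window_genes = proximity_annotate(
            cons[["locus_id", "chrom", "pos_bp"]], genes,
            windows=sig_windows)
        snp_genes.to_csv(out / "outlier_gene_annotation.tsv", sep="\t",
                         index=False)
        if window_genes is not None:
            window_genes.to_csv(out / "window_gene_annotation.tsv", sep="\t",
                                index=False)
        info["stages"].append("annotate")
        report_lines.append(f"annotate: {int((snp_genes['genes'] != '').sum())} "
                            f"outliers within 5 kb of a gene")

    info["runtime_s"] = round(time.time() - t0, 2)
    (out / "run_info.json").write_text(json.dumps(info, indent=2))
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    return out


def _synthetic_gene_set(seed: int, n_genes: int = 800) -> pd.DataFrame:
    """Synthetic gene intervals for annotation demos when no GFF/BED is
    supplied (uniformly placed 2-20 kb 'genes' on the simulated genome)."""
    rng = np.random.default_rng(seed + 7)
    chrom = rng.integers(1, simulate.N_CHROMS + 1, size=n_genes)
    start = rng.integers(0, simulate.CHROM_LENGTH_BP - 20_000, size=n_genes)
    length = rng.integers(2_000, 20_000, size=n_genes)
    return pd.DataFrame({
        "chrom": [f"chr{c}" for c in chrom],
        "start": start,
        "end": start + length,
        "strand": rng.choice(["+", "-"], size=n_genes),
        "gene_name": [f"gene{i:04d}" for i in range(n_genes)],
    }).sort_values(["chrom", "start"]).reset_index(drop=True)
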