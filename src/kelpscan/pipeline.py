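"""Pipeline orchestration: simulate/load -> filter -> stats -> ld -> roh -> scan.

All outputs are single-header TSV files with ``NA`` as the missing marker.
A manifest (JSON) records the configuration echo, input checksums, per-stage
row counts and wall time.  Runs are deterministic for a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

import kelpscan
from kelpscan import diversity, ld, roh, selection
from kelpscan import variant_io as vio
from kelpscan.synthetic_data import SimulationConfig, simulate_populations, synthetic_genes, write_truth

logger = logging.getLogger("kelpscan.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


class ValidationError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # inputs: exactly one of (vcf [+ popmap]) or simulation
    vcf: str | None = None
    popmap: str | None = None
    genes_bed: str | None = None
    contig_lengths: str | None = None
    simulation: SimulationConfig | dict | None = None
    # variant filters
    snps_only: bool = True
    biallelic_only: bool = True
    maf_min: float = 0.0
    max_missing: float = 1.0
    min_qual: float | None = None
    # windows (defaults follow the study design: 10 kb summary,
    # 250 kb Manhattan, 50 kb scan)
    summary_window: int = 10_000
    manhattan_window: int = 250_000
    scan_window: int = 50_000
    pairs: list = field(default_factory=list)       # [[focal, reference], ...]
    max_missing_site: float = 0.5
    # LD
    ld_groups: list = field(default_factory=list)   # default: every population
    ld_max_dist: int = 100_000
    ld_bin: int = 1_000
    ld_max_pairs: int | None = 200_000
    # ROH
    roh_min_snps: int = 50
    roh_min_length: int = 100_000
    roh_max_het: int = 1
    roh_max_gap: int = 1_000_000
    # scan
    threshold: float = 0.025
    merge_adjacent: bool = False
    make_plots: bool = False

    def validate(self) -> None:
        if (self.vcf is None) == (self.simulation is None):
            raise ValidationError(
                "exactly one of 'vcf' and 'simulation' must be supplied")
        if self.vcf is not None and self.popmap is None:
            raise ValidationError("a population map is required with a VCF input")
        for name in ("summary_window", "manhattan_window", "scan_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if isinstance(raw.get("simulation"), dict):
            sim = dict(raw["simulation"])
            if "sweep_loci" in sim:
                from kelpscan.synthetic_data import SweepLocus
                sim["sweep_loci"] = tuple(
                    SweepLocus(int(c), int(p), float(s)) for c, p, s in sim["sweep_loci"])
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksums: dict
    row_counts: dict
    wall_time_s: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _safe(name: str) -> str:
    return name.replace("|", "_vs_").replace(":", "_vs_").replace("/", "_")


def load_inputs(config: RunConfig):
    """(matrix, popmap, genes, contigs, truth_or_None) from VCF or simulation."""
    if config.simulation is not None:
        sim = config.simulation
        if isinstance(sim, dict):
            sim = SimulationConfig(**sim)
        matrix, popmap, truth = simulate_populations(sim)
        contigs = dict(matrix.contig_lengths or {})
        genes = (vio.read_bed(config.genes_bed) if config.genes_bed
                 else synthetic_genes(contigs))
        return matrix, popmap, genes, contigs, truth
    matrix = vio.read_vcf(config.vcf)
    popmap = vio.read_popmap(config.popmap)
    popmap.validate_against(matrix)
    if config.contig_lengths:
        contigs = vio.read_contig_lengths(config.contig_lengths)
    elif matrix.contig_lengths:
        contigs = dict(matrix.contig_lengths)
    else:
        contigs = {c: int(matrix.pos[matrix.chrom == c].max())
                   for c in dict.fromkeys(matrix.chrom)}
    genes = vio.read_bed(config.genes_bed) if config.genes_bed else pd.DataFrame(
        columns=["chrom", "start", "end", "name"])
    return matrix, popmap, genes, contigs, None


def compare_groups(config: RunConfig, matrix=None, popmap=None, contigs=None):
    """Per configured pair: the F_ST/ROD/delta-D DCMS scan table.

    Groups may be population labels or categories; a group with fewer than
    two samples is an error naming the group.
    """
    if matrix is None:
        matrix, popmap, _, contigs, _ = load_inputs(config)
    windows = vio.make_windows(contigs, config.scan_window)
    tables: dict[str, pd.DataFrame] = {}
    for focal, reference in (tuple(p) for p in config.pairs):
        for group in (focal, reference):
            if len(popmap.resolve_group(group)) < 2:
                raise ValidationError(f"group {group!r} has fewer than 2 samples")
        pair = diversity.pair_window_stats(
            matrix, popmap.resolve_group(focal), popmap.resolve_group(reference),
            windows, config.max_missing_site)
        scan, _ = selection.dcms_scan(pair, threshold=config.threshold)
        tables[f"{focal}|{reference}"] = scan
    return tables


def run_full(config: RunConfig) -> RunManifest:
    """Execute every stage, writing all tables plus a manifest to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    logging.getLogger("kelpscan").addHandler(log_handler)
    row_counts: dict[str, int] = {}
    wall: dict[str, float] = {}
    checksums: dict[str, str] = {}
    staged: list[Path] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            staged.clear()
            try:
                fn()
            except Exception as exc:
                for p in staged:
                    if p.exists():
                        p.rename(p.with_suffix(p.suffix + ".partial"))
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            wall[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: done in %.2fs", name, wall[name])
        return deco

    def emit(df: pd.DataFrame, name: str, count_key: str | None = None) -> None:
        path = out / name
        staged.append(path)
        _write_tsv(df, path)
        row_counts[count_key or name] = len(df)

    state: dict[str, Any] = {}

    @stage("inputs")
    def _inputs():
        for p in (config.vcf, config.popmap, config.genes_bed, config.contig_lengths):
            if p:
                checksums[str(p)] = _sha256(p)
        matrix, popmap, genes, contigs, truth = load_inputs(config)
        state.update(matrix=matrix, popmap=popmap, genes=genes, contigs=contigs)
        if truth is not None:
            path = out / "truth.tsv"
            staged.append(path)
            write_truth(truth, path)
        if config.simulation is not None:
            path = out / "simulated.vcf"
            staged.append(path)
            vio.write_vcf(matrix, path)
            vio.write_popmap(popmap, out / "popmap.tsv")
            vio.write_bed(genes, out / "genes.bed")
            vio.write_contig_lengths(contigs, out / "contigs.tsv")
        row_counts["input_sites"] = matrix.n_sites
        row_counts["input_samples"] = matrix.n_samples

    @stage("filter")
    def _filter():
        matrix, report = vio.filter_variants(
            state["matrix"], snps_only=config.snps_only,
            biallelic_only=config.biallelic_only, maf_min=config.maf_min,
            max_missing=config.max_missing, min_qual=config.min_qual)
        state["matrix"] = matrix
        emit(pd.DataFrame([dataclasses.asdict(report)]), "filter_report.tsv")
        row_counts["filtered_sites"] = matrix.n_sites

    @stage("stats")
    def _stats():
        matrix, popmap, contigs = state["matrix"], state["popmap"], state["contigs"]
        pairs = [tuple(p) for p in config.pairs]
        for size, label in ((config.summary_window, "summary"),
                            (config.manhattan_window, "manhattan")):
            windows = vio.make_windows(contigs, size)
            table = diversity.window_stat_table(matrix, popmap, windows,
                                                max_missing_site=config.max_missing_site)
            emit(table, f"windows_{label}_{size}.tsv")
        windows = vio.make_windows(contigs, config.scan_window)
        table = diversity.window_stat_table(matrix, popmap, windows, pairs=pairs,
                                            max_missing_site=config.max_missing_site)
        emit(table, f"windows_scan_{config.scan_window}.tsv")
        state["scan_windows"] = windows

    @stage("ld")
    def _ld():
        matrix, popmap = state["matrix"], state["popmap"]
        groups = config.ld_groups or popmap.populations
        rows = []
        for group in groups:
            profile = ld.ld_decay_profile(
                matrix, popmap.resolve_group(group), config.ld_max_dist,
                config.ld_bin, max_pairs=config.ld_max_pairs, seed=config.seed)
            df = ld.profile_to_frame(profile)
            df.insert(0, "group", group)
            rows.append(df)
            rows.append(pd.DataFrame([{
                "group": group, "bin_start": "half_decay_distance",
                "bin_end": "NA", "mean_r2": profile.half_decay_distance,
                "n_pairs": int(profile.n_pairs.sum())}]))
        emit(pd.concat(rows, ignore_index=True), "ld_decay.tsv")

    @stage("roh")
    def _roh():
        matrix = state["matrix"]
        segments = roh.detect_roh_all(
            matrix, min_snps=config.roh_min_snps,
            min_length_bp=config.roh_min_length, max_het=config.roh_max_het,
            max_gap_bp=config.roh_max_gap)
        emit(roh.segments_to_frame(segments), "roh_segments.tsv")
        emit(roh.roh_summary(segments, matrix.sample_ids), "roh_summary.tsv")

    @stage("scan")
    def _scan():
        matrix, popmap, genes = state["matrix"], state["popmap"], state["genes"]
        tables = compare_groups(config, matrix, popmap, state["contigs"])
        for pair_name, scan_df in tables.items():
            tag = _safe(pair_name)
            emit(scan_df, f"dcms_{tag}.tsv")
            sig = selection.significant_windows(scan_df, config.threshold)
            emit(sig, f"significant_{tag}.tsv")
            if len(genes):
                report = selection.genes_in_windows(
                    sig, genes, merge_adjacent=config.merge_adjacent)
                emit(report.genes, f"genes_{tag}.tsv")
                row_counts[f"genes_{tag}"] = report.n_genes

    if config.make_plots:
        @stage("plots")
        def _plots():
            from kelpscan import plots
            for pair_name in (f"{a}|{b}" for a, b in (tuple(p) for p in config.pairs)):
                tag = _safe(pair_name)
                df = pd.read_csv(out / f"dcms_{tag}.tsv", sep="\t", na_values="NA")
                plots.manhattan(df, "dcms", out / f"dcms_{tag}.png",
                                threshold_col="p_dcms", threshold=config.threshold)
            ld_df = pd.read_csv(out / "ld_decay.tsv", sep="\t", na_values="NA")
            plots.ld_curves(ld_df, out / "ld_decay.png")

    manifest = RunManifest(
        config={k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in dataclasses.asdict(config).items()},
        version=kelpscan.__version__,
        input_checksums=checksums,
        row_counts=row_counts,
        wall_time_s=wall,
    )
    manifest.write(out / "manifest.json")
    logging.getLogger("kelpscan").removeHandler(log_handler)
    log_handler.close()
    return manifest
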