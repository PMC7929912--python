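"""Genotype matrix I/O, variant filtering and genomic window construction.

Conventions
-----------
* VCF positions are 1-based; windows and BED intervals are 0-based half-open.
* Genotypes are coded per sample x site as 0 (hom-ref), 1 (het), 2 (hom-alt)
  and :data:`MISSING` (= -1) for missing or half-missing calls.  For records
  with several ALT alleles the code is the count of non-reference alleles;
  such records are normally removed by :func:`filter_variants`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Code for a missing (or half-missing) genotype call.
MISSING = -1

_VALID_CATEGORIES = ("natural", "cultivated", "introduced")
_SNP_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF record violates the expected diploid GT layout."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes for samples x ordered variant sites.

    Sites are ordered by (chromosome, position) with positions strictly
    increasing within each chromosome.
    """

    sample_ids: list[str]
    chrom: np.ndarray          # object array of chromosome ids, per site
    pos: np.ndarray            # int64, 1-based positions
    ref: np.ndarray            # object array of REF alleles
    alt: np.ndarray            # object array of ALT alleles (comma-joined)
    genotypes: np.ndarray      # int8, shape (n_samples, n_sites)
    qual: np.ndarray | None = None          # float per site, NaN when absent
    contig_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        n_samples, n_sites = self.genotypes.shape
        if n_samples != len(self.sample_ids):
            raise ValueError("genotype rows do not match sample_ids")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length does not match genotype columns")
        if self.qual is not None:
            self.qual = np.asarray(self.qual, dtype=float)
            if len(self.qual) != n_sites:
                raise ValueError("qual length does not match genotype columns")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {MISSING, 0, 1, 2}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set[str] = set()
        last_chrom = None
        last_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != last_chrom:
                if c in seen:
                    raise ValueError(f"sites not grouped by chromosome at {c}:{p}")
                seen.add(c)
                last_chrom = c
                last_pos = -1
            if p <= last_pos:
                raise ValueError(
                    f"positions not strictly increasing at {c}:{p}")
            last_pos = p

    # -- shape helpers ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        """Row indices of the given sample ids (raising on unknown ids)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Site indices with 1-based position p satisfying start <= p-1 < end."""
        on_chrom = np.flatnonzero(self.chrom == chrom)
        if on_chrom.size == 0:
            return on_chrom
        p0 = self.pos[on_chrom] - 1
        lo = np.searchsorted(p0, start, side="left")
        hi = np.searchsorted(p0, end, side="left")
        return on_chrom[lo:hi]

    def subset(self, samples: Sequence[str] | None = None,
               sites: np.ndarray | None = None) -> "GenotypeMatrix":
        rows = (self.sample_indices(samples) if samples is not None
                else np.arange(self.n_samples))
        cols = np.asarray(sites, dtype=np.intp) if sites is not None else np.arange(self.n_sites)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            chrom=self.chrom[cols],
            pos=self.pos[cols],
            ref=self.ref[cols],
            alt=self.alt[cols],
            genotypes=self.genotypes[np.ix_(rows, cols)],
            qual=None if self.qual is None else self.qual[cols],
            contig_lengths=dict(self.contig_lengths) if self.contig_lengths else None,
        )

    def equal(self, other: "GenotypeMatrix") -> bool:
        return (self.sample_ids == other.sample_ids
                and np.array_equal(self.chrom, other.chrom)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.ref, other.ref)
                and np.array_equal(self.alt, other.alt)
                and np.array_equal(self.genotypes, other.genotypes))


@dataclass(frozen=True)
class Window:
    """A 0-based half-open genomic interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PopulationMap:
    """sample id -> (population label, category)."""

    entries: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for sample, (pop, cat) in self.entries.items():
            if cat not in _VALID_CATEGORIES:
                raise ValueError(
                    f"sample {sample!r}: category {cat!r} not in {_VALID_CATEGORIES}")

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for pop, _ in self.entries.values():
            if pop not in out:
                out.append(pop)
        return out

    def population_of(self, sample: str) -> str:
        return self.entries[sample][0]

    def category_of_population(self, population: str) -> str:
        for pop, cat in self.entries.values():
            if pop == population:
                return cat
        raise KeyError(f"unknown population {population!r}")

    def samples_in(self, population: str) -> list[str]:
        return [s for s, (p, _) in self.entries.items() if p == population]

    def samples_in_category(self, category: str) -> list[str]:
        return [s for s, (_, c) in self.entries.items() if c == category]

    def resolve_group(self, group: str) -> list[str]:
        """Samples of a population label, or of a whole category."""
        if group in _VALID_CATEGORIES:
            samples = self.samples_in_category(group)
        else:
            samples = self.samples_in(group)
        if not samples:
            raise KeyError(f"group {group!r} matches no samples")
        return samples

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.entries]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")


@dataclass
class FilterReport:
    """Per-rule accounting of a :func:`filter_variants` pass.

    Rules are applied in a fixed order and each removed record is attributed
    to the first rule it fails, so n_input = n_retained + sum(removed).
    """

    n_input: int = 0
    removed_qual: int = 0
    removed_non_snp: int = 0
    removed_multiallelic: int = 0
    removed_callrate: int = 0
    removed_maf: int = 0
    n_retained: int = 0

    def check(self) -> None:
        total = (self.removed_qual + self.removed_non_snp + self.removed_multiallelic
                 + self.removed_callrate + self.removed_maf + self.n_retained)
        if total != self.n_input:
            raise AssertionError("filter report does not balance")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF 4.x file with per-sample GT fields into a genotype matrix.

    Phasing separators are ignored; half-missing calls become MISSING.
    Raises :class:`VcfParseError` for non-diploid calls, absent GT data or
    unsorted records, naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contig_lengths: dict[str, int] = {}
    try:
        for name, length in zip(vcf.seqnames, vcf.seqlens):
            contig_lengths[name] = int(length)
    except Exception:  # header without contig lengths
        contig_lengths = {}

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    codes: list[np.ndarray] = []
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"
        gts = var.genotypes
        if gts is None:
            raise VcfParseError(f"record {where} has no GT field")
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) != 3:  # [allele, allele, phased] for diploids
                raise VcfParseError(
                    f"record {where}, sample {samples[i]}: non-diploid call")
            a, b = g[0], g[1]
            row[i] = MISSING if (a < 0 or b < 0) else int(a > 0) + int(b > 0)
        chroms.append(var.CHROM)
        poss.append(int(var.POS))
        refs.append(var.REF)
        alts.append(",".join(var.ALT) if var.ALT else ".")
        quals.append(float(var.QUAL) if var.QUAL is not None else np.nan)
        codes.append(row)

    genotypes = (np.stack(codes, axis=1) if codes
                 else np.empty((len(samples), 0), dtype=np.int8))
    try:
        return GenotypeMatrix(
            sample_ids=samples,
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            alt=np.array(alts, dtype=object),
            genotypes=genotypes,
            qual=np.array(quals, dtype=float),
            contig_lengths=contig_lengths or None,
        )
    except ValueError as exc:
        raise VcfParseError(f"unsorted or malformed VCF {path}: {exc}") from exc


_GT_STRING = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with unphased GT fields and contig header lines."""
    contigs: dict[str, int] = dict(matrix.contig_lengths or {})
    for c, p in zip(matrix.chrom, matrix.pos):
        contigs[c] = max(contigs.get(c, 0), int(p))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kelpscan\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if matrix.sample_ids:
            cols += ["FORMAT"] + list(matrix.sample_ids)
        fh.write("\t".join(cols) + "\n")
        qual = matrix.qual
        for j in range(matrix.n_sites):
            q = "." if qual is None or np.isnan(qual[j]) else f"{qual[j]:g}"
            fields = [str(matrix.chrom[j]), str(matrix.pos[j]), ".",
                      str(matrix.ref[j]), str(matrix.alt[j]), q, ".", "."]
            if matrix.sample_ids:
                fields.append("GT")
                fields.extend(_GT_STRING[int(g)] for g in matrix.genotypes[:, j])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _is_snp(ref: str, alt: str) -> bool:
    if len(ref) != 1 or ref not in _SNP_BASES:
        return False
    alleles = alt.split(",")
    return all(len(a) == 1 and a in _SNP_BASES for a in alleles)


def filter_variants(matrix: GenotypeMatrix, *,
                    snps_only: bool = True,
                    biallelic_only: bool = True,
                    maf_min: float = 0.0,
                    max_missing: float = 1.0,
                    min_qual: float | None = None,
                    ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply site filters; attribution is to the first failing rule.

    Rule order: QUAL -> SNP -> biallelic -> call-rate -> MAF.  MAF is computed
    on non-missing alleles only; ``max_missing`` is the maximum tolerated
    fraction of missing genotype calls per site.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= max_missing <= 1.0):
        raise ValueError("maf_min and max_missing must lie in [0, 1]")
    report = FilterReport(n_input=matrix.n_sites)
    keep = np.ones(matrix.n_sites, dtype=bool)
    g = matrix.genotypes
    n_samples = max(matrix.n_samples, 1)
    miss_frac = (g == MISSING).sum(axis=0) / n_samples
    nonmiss = (g != MISSING).sum(axis=0)
    alt_alleles = np.where(g == MISSING, 0, g).sum(axis=0)
    tot_alleles = 2 * nonmiss
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(tot_alleles > 0, alt_alleles / np.maximum(tot_alleles, 1), np.nan)
        maf = np.minimum(af, 1.0 - af)

    for j in range(matrix.n_sites):
        if min_qual is not None:
            q = np.nan if matrix.qual is None else matrix.qual[j]
            if np.isnan(q) or q < min_qual:
                report.removed_qual += 1
                keep[j] = False
                continue
        if snps_only and not _is_snp(str(matrix.ref[j]), str(matrix.alt[j])):
            report.removed_non_snp += 1
            keep[j] = False
            continue
        if biallelic_only and "," in str(matrix.alt[j]):
            report.removed_multiallelic += 1
            keep[j] = False
            continue
        if miss_frac[j] > max_missing:
            report.removed_callrate += 1
            keep[j] = False
            continue
        if maf_min > 0 and (np.isnan(maf[j]) or maf[j] < maf_min):
            report.removed_maf += 1
            keep[j] = False
            continue
    report.n_retained = int(keep.sum())
    report.check()
    return matrix.subset(sites=np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(contig_lengths: Mapping[str, int], size: int) -> list[Window]:
    """Tile each contig with non-overlapping windows of ``size`` bp.

    The last window of a contig is truncated at the contig length; every bp
    is covered exactly once.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    windows: list[Window] = []
    for chrom, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {chrom!r} has non-positive length")
        start = 0
        while start < length:
            windows.append(Window(chrom, start, min(start + size, length)))
            start += size
    return windows


# ---------------------------------------------------------------------------
# Tabular side files
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> PopulationMap:
    entries: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample":  # optional header
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            entries[parts[0]] = (parts[1], parts[2])
    return PopulationMap(entries)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tcategory\n")
        for sample, (pop, cat) in popmap.entries.items():
            fh.write(f"{sample}\t{pop}\t{cat}\n")


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
    return out


def write_contig_lengths(contigs: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in contigs.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+name records (0-based half-open) into a data frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "name"])
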