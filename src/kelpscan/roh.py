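"""Runs of homozygosity (ROH): per-individual homozygous tract detection.

The detector is a deterministic greedy left-to-right scan over the
individual's non-missing genotype calls on each chromosome: a run may contain
at most ``max_het`` heterozygous calls and no gap between consecutive
non-missing calls larger than ``max_gap_bp``; heterozygous calls are trimmed
from run ends, and runs shorter than ``min_length_bp`` or with fewer than
``min_snps`` calls are discarded.  Missing genotypes neither break nor extend
a run (they only contribute to positional gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from kelpscan.variant_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous tract of one individual."""

    sample: str
    chrom: str
    start: int       # 1-based position of first SNP in the run
    end: int         # 1-based position of last SNP in the run
    n_snps: int
    n_het: int       # heterozygous calls retained inside the run

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_roh(matrix: GenotypeMatrix, sample: str, *,
               min_snps: int = 50, min_length_bp: int = 100_000,
               max_het: int = 1, max_gap_bp: int = 1_000_000,
               ) -> list[ROHSegment]:
    """Detect ROH segments for one sample across all chromosomes."""
    row = matrix.sample_indices([sample])[0]
    g = matrix.genotypes[row]
    segments: list[ROHSegment] = []
    for chrom in dict.fromkeys(matrix.chrom):
        on = np.flatnonzero((matrix.chrom == chrom) & (g != MISSING))
        pos = matrix.pos[on]
        het = matrix.genotypes[row, on] == 1
        segments.extend(_scan_chrom(sample, str(chrom), pos, het,
                                    min_snps, min_length_bp, max_het, max_gap_bp))
    return segments


def _scan_chrom(sample: str, chrom: str, pos: np.ndarray, het: np.ndarray,
                min_snps: int, min_length_bp: int, max_het: int,
                max_gap_bp: int) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    m = len(pos)
    i = 0
    while i < m:
        # skip heterozygous starts when no het budget remains to absorb them
        j = i
        het_cnt = int(het[i])
        if het_cnt > max_het:
            i += 1
            continue
        blocked_by_het = False
        while j + 1 < m:
            if pos[j + 1] - pos[j] > max_gap_bp:
                break
            if het[j + 1] and het_cnt == max_het:
                blocked_by_het = True
                break
            het_cnt += int(het[j + 1])
            j += 1
        _emit(out, sample, chrom, pos, het, i, j,
              min_snps, min_length_bp)
        i = j + 2 if blocked_by_het else j + 1
    return out


def _emit(out: list[ROHSegment], sample: str, chrom: str,
          pos: np.ndarray, het: np.ndarray, s: int, e: int,
          min_snps: int, min_length_bp: int) -> None:
    while s <= e and het[s]:
        s += 1
    while e >= s and het[e]:
        e -= 1
    if e < s:
        return
    n_snps = e - s + 1
    length = int(pos[e] - pos[s] + 1)
    if n_snps >= min_snps and length >= min_length_bp:
        out.append(ROHSegment(sample, chrom, int(pos[s]), int(pos[e]),
                              n_snps, int(het[s:e + 1].sum())))


def detect_roh_all(matrix: GenotypeMatrix, **kwargs) -> list[ROHSegment]:
    """ROH for every sample in the matrix."""
    segments: list[ROHSegment] = []
    for sample in matrix.sample_ids:
        segments.extend(detect_roh(matrix, sample, **kwargs))
    return segments


def roh_summary(segments: Iterable[ROHSegment],
                samples: Sequence[str]) -> pd.DataFrame:
    """Per-sample total/mean segment length and count.

    Samples without segments are reported with total 0 and NaN mean.
    """
    totals = {s: 0 for s in samples}
    counts = {s: 0 for s in samples}
    for seg in segments:
        if seg.sample not in totals:
            raise KeyError(f"segment for unknown sample {seg.sample!r}")
        totals[seg.sample] += seg.length
        counts[seg.sample] += 1
    rows = []
    for s in samples:
        n = counts[s]
        rows.append({
            "sample": s,
            "n_segments": n,
            "total_length": totals[s],
            "mean_length": totals[s] / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def segments_to_frame(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample": s.sample, "chrom": s.chrom, "start": s.start, "end": s.end,
          "length": s.length, "n_snps": s.n_snps, "n_het": s.n_het}
         for s in segments],
        columns=["sample", "chrom", "start", "end", "length", "n_snps", "n_het"],
    )
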