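"""Pairwise genotype r-squared and distance-binned LD decay profiles.

LD is the squared Pearson correlation of unphased genotype dosages
(Rogers-Huff style composite LD); no haplotype phase is inferred.  The decay
profile bins intra-chromosome site pairs by physical separation, and the
half-decay distance is the interpolated separation at which binned mean r2
first falls to half the first populated bin's mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from kelpscan.variant_io import MISSING, GenotypeMatrix


@dataclass
class LDDecayProfile:
    """Distance-binned mean r2 with pair counts and a half-decay summary."""

    bin_edges: np.ndarray      # length n_bins + 1, bp
    mean_r2: np.ndarray        # length n_bins, NaN for empty bins
    n_pairs: np.ndarray        # length n_bins, defined-r2 pairs per bin
    half_decay_distance: float  # bp, NaN when the profile never halves

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def genotype_r2(g1: Sequence[int], g2: Sequence[int]) -> float:
    """Squared Pearson correlation of dosage codes over complete pairs.

    NaN when fewer than 3 pairwise-complete entries remain or either vector
    is constant.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _enumerate_pairs(matrix: GenotypeMatrix, cols: np.ndarray, max_dist: int,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All intra-chromosome site-index pairs with separation in (0, max_dist]."""
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    for chrom in dict.fromkeys(matrix.chrom[cols]):
        cc = cols[matrix.chrom[cols] == chrom]
        pos = matrix.pos[cc]
        order = np.argsort(pos, kind="stable")
        cc, pos = cc[order], pos[order]
        for k in range(len(cc) - 1):
            hi = np.searchsorted(pos, pos[k] + max_dist, side="right")
            if hi > k + 1:
                jj.append(cc[k + 1:hi])
                ii.append(np.full(hi - k - 1, cc[k], dtype=np.intp))
    if not ii:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty, np.empty(0, dtype=np.int64)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    dist = np.abs(matrix.pos[j] - matrix.pos[i])
    return i, j, dist


def _pairwise_r2(g: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """r2 for index pairs of the (samples x sites) dosage matrix ``g``."""
    has_missing = (g == MISSING).any()
    if not has_missing:
        x = g.astype(float)
        x -= x.mean(axis=0)
        sd = x.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = x / sd
        r = np.einsum("ki,ki->i", z[:, i], z[:, j]) / g.shape[0]
        out = r * r
        out[(sd[i] == 0) | (sd[j] == 0)] = np.nan
        if g.shape[0] < 3:
            out[:] = np.nan
        return out
    return np.array([genotype_r2(g[:, a], g[:, b]) for a, b in zip(i, j)])


def ld_decay_profile(matrix: GenotypeMatrix, samples: Sequence[str],
                     max_dist: int, bin_width: int,
                     max_pairs: int | None = None,
                     seed: int | None = None,
                     max_missing_site: float = 1.0) -> LDDecayProfile:
    """Binned mean genotype r2 against physical separation for one group.

    All intra-chromosome pairs with separation <= ``max_dist`` are used; when
    ``max_pairs`` is given, a seeded uniform subsample of that size is taken
    instead.  Undefined r2 values (constant sites, too few complete pairs)
    are excluded from bin means.
    """
    if max_dist <= 0 or bin_width <= 0:
        raise ValueError("max_dist and bin_width must be positive")
    rows = matrix.sample_indices(samples)
    cols = np.arange(matrix.n_sites)
    if max_missing_site < 1.0 and rows.size:
        miss = (matrix.genotypes[rows] == MISSING).mean(axis=0)
        cols = cols[miss <= max_missing_site]
    i, j, dist = _enumerate_pairs(matrix, cols, max_dist)
    if max_pairs is not None and i.size > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(i.size, size=max_pairs, replace=False)
        pick.sort()
        i, j, dist = i[pick], j[pick], dist[pick]

    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    edges[-1] = max(edges[-1], max_dist)
    mean_r2 = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    if i.size:
        r2 = _pairwise_r2(matrix.genotypes[rows], i, j)
        ok = np.isfinite(r2)
        which = np.minimum((dist[ok] - 1) // bin_width, n_bins - 1).astype(np.intp)
        counts = np.bincount(which, minlength=n_bins)
        sums = np.bincount(which, weights=r2[ok], minlength=n_bins)
        n_pairs = counts
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    profile = LDDecayProfile(edges, mean_r2, n_pairs, np.nan)
    profile.half_decay_distance = half_decay_distance(profile)
    return profile


def half_decay_distance(profile: LDDecayProfile) -> float:
    """Distance at which binned mean r2 first drops to half its maximum.

    The maximum is the mean r2 of the first populated bin; the crossing is
    linearly interpolated between bin midpoints.  NaN when the target level
    is never reached within the profile.
    """
    populated = np.isfinite(profile.mean_r2) & (profile.n_pairs > 0)
    if populated.sum() < 2:
        return np.nan
    mids = profile.midpoints[populated]
    means = profile.mean_r2[populated]
    maximum = means[0]
    if maximum <= 0:
        return np.nan
    target = maximum / 2.0
    for k in range(1, len(means)):
        if means[k] <= target:
            lo, hi = means[k - 1], means[k]
            if lo == hi:
                return float(mids[k])
            frac = (lo - target) / (lo - hi)
            return float(mids[k - 1] + frac * (mids[k] - mids[k - 1]))
    return np.nan


def profile_to_frame(profile: LDDecayProfile):
    """Tabular view of a profile (one row per bin)."""
    import pandas as pd

    return pd.DataFrame({
        "bin_start": profile.bin_edges[:-1],
        "bin_end": profile.bin_edges[1:],
        "mean_r2": profile.mean_r2,
        "n_pairs": profile.n_pairs,
    })
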