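"""Windowed diversity and differentiation statistics.

Within-population: nucleotide diversity (pi), Watterson's theta, Tajima's D,
expected/observed heterozygosity and F_IS.  Between-population: Weir &
Cockerham (1984) F_ST (ratio-of-sums over sites), reduction of diversity
(ROD) and the focal-minus-reference difference of Tajima's D.

pi and theta are reported per bp, dividing by the full window length, so
unlisted (invariant) sites count as monomorphic.  Undefined values are NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from kelpscan.variant_io import MISSING, GenotypeMatrix, PopulationMap, Window

logger = logging.getLogger(__name__)

#: Sites with a higher within-group missing-call fraction are excluded from
#: that group's window statistics.
DEFAULT_MAX_MISSING_SITE = 0.5


# ---------------------------------------------------------------------------
# Allele-count plumbing
# ---------------------------------------------------------------------------

def _group_counts(matrix: GenotypeMatrix, rows: np.ndarray, cols: np.ndarray,
                  max_missing_site: float = DEFAULT_MAX_MISSING_SITE,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (alt alleles, total alleles, het individuals, non-missing
    individuals) for a sample group, plus the retained column indices.

    Sites that are entirely missing, or miss more than ``max_missing_site`` of
    the group's calls, are dropped (and logged at debug level).
    """
    g = matrix.genotypes[np.ix_(rows, cols)]
    miss = g == MISSING
    n_ind = (~miss).sum(axis=0)
    ok = n_ind > 0
    if max_missing_site < 1.0 and len(rows):
        ok &= miss.sum(axis=0) / len(rows) <= max_missing_site
    if not ok.all():
        logger.debug("excluding %d sites with excessive missingness", (~ok).sum())
    g = g[:, ok]
    miss = miss[:, ok]
    alt = np.where(miss, 0, g).sum(axis=0)
    het = (g == 1).sum(axis=0)
    n_ind = n_ind[ok]
    return alt, 2 * n_ind, het, n_ind, cols[ok]


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------

def site_pi(alt_count: int, total_count: int) -> float:
    """Unbiased per-site heterozygosity 2 j (n-j) / (n (n-1))."""
    n = total_count
    if n < 2:
        return np.nan
    j = alt_count
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def _site_pi_vec(alt: np.ndarray, tot: np.ndarray) -> np.ndarray:
    alt = np.asarray(alt, dtype=float)
    tot = np.asarray(tot, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * alt * (tot - alt) / (tot * (tot - 1.0))
    out[tot < 2] = np.nan
    return out


def harmonic(k: int) -> float:
    """a1 = sum_{i=1}^{k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def watterson_theta(n_snps: int, n_alleles: int, length_bp: int) -> float:
    """Watterson's per-bp estimator S / (a1 * L)."""
    if n_alleles < 2:
        return np.nan
    return n_snps / (harmonic(n_alleles - 1) * length_bp)


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) normalising constants of Tajima (1989) for n alleles."""
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajima_d_from_counts(alt: np.ndarray, tot: np.ndarray) -> float:
    """Tajima's D from per-site alt/total allele counts.

    The sample size n is the rounded mean of per-site totals (they coincide
    when there is no missingness).  NaN when there are no segregating sites
    or fewer than 4 alleles.
    """
    alt = np.asarray(alt)
    tot = np.asarray(tot)
    seg = (alt > 0) & (alt < tot) & (tot >= 2)
    s = int(seg.sum())
    if s == 0:
        return np.nan
    n = int(round(float(np.mean(tot[seg]))))
    if n < 4:
        return np.nan
    pi_sum = float(np.nansum(_site_pi_vec(alt[seg], tot[seg])))
    a1 = harmonic(n - 1)
    e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return np.nan
    return (pi_sum - s / a1) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Window-level statistics
# ---------------------------------------------------------------------------

def window_pi(matrix: GenotypeMatrix, window: Window, samples: Sequence[str],
              max_missing_site: float = DEFAULT_MAX_MISSING_SITE,
              ) -> tuple[float, int]:
    """(per-bp pi, number of segregating sites) for one window and group."""
    rows = matrix.sample_indices(samples)
    cols = matrix.sites_in(window.chrom, window.start, window.end)
    alt, tot, _, _, _ = _group_counts(matrix, rows, cols, max_missing_site)
    seg = (alt > 0) & (alt < tot)
    pi_sum = float(np.nansum(_site_pi_vec(alt, tot)))
    return pi_sum / window.length, int(seg.sum())


def tajimas_d(matrix: GenotypeMatrix, window: Window, samples: Sequence[str],
              max_missing_site: float = DEFAULT_MAX_MISSING_SITE) -> float:
    rows = matrix.sample_indices(samples)
    cols = matrix.sites_in(window.chrom, window.start, window.end)
    alt, tot, _, _, _ = _group_counts(matrix, rows, cols, max_missing_site)
    return tajima_d_from_counts(alt, tot)


def expected_observed_het(matrix: GenotypeMatrix, window: Window,
                          samples: Sequence[str],
                          max_missing_site: float = DEFAULT_MAX_MISSING_SITE,
                          ) -> tuple[float, float]:
    """Mean unbiased H_e and observed H_o over variant sites in a window."""
    rows = matrix.sample_indices(samples)
    cols = matrix.sites_in(window.chrom, window.start, window.end)
    alt, tot, het, n_ind, _ = _group_counts(matrix, rows, cols, max_missing_site)
    seg = (alt > 0) & (alt < tot) & (tot >= 2)
    if not seg.any():
        return np.nan, np.nan
    p = alt[seg] / tot[seg]
    he = 2.0 * p * (1.0 - p) * tot[seg] / (tot[seg] - 1.0)
    ho = het[seg] / n_ind[seg]
    return float(np.mean(he)), float(np.mean(ho))


def inbreeding_fis(he: float, ho: float) -> float:
    """F_IS = 1 - Ho/He; NaN when He is 0 or undefined."""
    if not np.isfinite(he) or he <= 0 or not np.isfinite(ho):
        return np.nan
    return 1.0 - ho / he


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------

def _wc_site_components(p: np.ndarray, n: np.ndarray, h: np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised WC84 variance components for 2 populations x many sites.

    p, n, h have shape (2, n_sites): alt-allele frequency, non-missing
    diploid sample count, and observed het fraction per population.
    """
    r = 2.0
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
    bad = (n.min(axis=0) < 1) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def weir_cockerham_fst(matrix: GenotypeMatrix, window: Window,
                       pop_a_samples: Sequence[str], pop_b_samples: Sequence[str],
                       max_missing_site: float = DEFAULT_MAX_MISSING_SITE) -> float:
    """Window WC84 theta-hat as the ratio of summed variance components."""
    cols = matrix.sites_in(window.chrom, window.start, window.end)
    stats = []
    for samples in (pop_a_samples, pop_b_samples):
        rows = matrix.sample_indices(samples)
        alt, tot, het, n_ind, kept = _group_counts(matrix, rows, cols, max_missing_site)
        stats.append((alt, tot, het, n_ind, kept))
    # restrict to sites retained in both groups
    common = np.intersect1d(stats[0][4], stats[1][4])
    if common.size == 0:
        return np.nan
    p = np.empty((2, common.size))
    n = np.empty((2, common.size))
    h = np.empty((2, common.size))
    for k, (alt, tot, het, n_ind, kept) in enumerate(stats):
        sel = np.isin(kept, common)
        p[k] = alt[sel] / tot[sel]
        n[k] = n_ind[sel]
        h[k] = het[sel] / n_ind[sel]
    a, b, c = _wc_site_components(p, n, h)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if not np.isfinite(den) or den == 0:
        return np.nan
    return float(num / den)


def rod(pi_focal: float, pi_reference: float) -> float:
    """Reduction of diversity 1 - pi_focal / pi_reference."""
    if not np.isfinite(pi_reference) or pi_reference <= 0 or not np.isfinite(pi_focal):
        return np.nan
    return 1.0 - pi_focal / pi_reference


def delta_tajima(d_focal: float, d_reference: float) -> float:
    """Focal-minus-reference Tajima's D, NaN-propagating."""
    if not np.isfinite(d_focal) or not np.isfinite(d_reference):
        return np.nan
    return d_focal - d_reference


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def population_window_stats(matrix: GenotypeMatrix, samples: Sequence[str],
                            windows: Sequence[Window],
                            max_missing_site: float = DEFAULT_MAX_MISSING_SITE,
                            ) -> pd.DataFrame:
    """Per-window pi, theta_W, Tajima's D, He, Ho and F_IS for one group."""
    rows = matrix.sample_indices(samples)
    records = []
    for w in windows:
        cols = matrix.sites_in(w.chrom, w.start, w.end)
        alt, tot, het, n_ind, _ = _group_counts(matrix, rows, cols, max_missing_site)
        seg = (alt > 0) & (alt < tot) & (tot >= 2)
        n_snps = int(seg.sum())
        pi = float(np.nansum(_site_pi_vec(alt, tot))) / w.length
        n_alleles = int(round(float(np.mean(tot[seg])))) if n_snps else 0
        theta = watterson_theta(n_snps, n_alleles, w.length) if n_snps else 0.0
        d = tajima_d_from_counts(alt, tot)
        if seg.any():
            p = alt[seg] / tot[seg]
            he = float(np.mean(2.0 * p * (1 - p) * tot[seg] / (tot[seg] - 1.0)))
            ho = float(np.mean(het[seg] / n_ind[seg]))
        else:
            he = ho = np.nan
        records.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "n_snps": n_snps, "callable_bp": w.length,
            "pi": pi, "theta_w": theta, "tajima_d": d,
            "he": he, "ho": ho, "fis": inbreeding_fis(he, ho),
        })
    return pd.DataFrame.from_records(records)


def pair_window_stats(matrix: GenotypeMatrix,
                      focal_samples: Sequence[str], ref_samples: Sequence[str],
                      windows: Sequence[Window],
                      max_missing_site: float = DEFAULT_MAX_MISSING_SITE,
                      ) -> pd.DataFrame:
    """Per-window F_ST, ROD and delta Tajima's D for a focal/reference pair.

    ROD and delta D are oriented focal-vs-reference: positive ROD and
    negative delta D indicate diversity loss / rare-variant excess in the
    focal group.
    """
    focal = population_window_stats(matrix, focal_samples, windows, max_missing_site)
    ref = population_window_stats(matrix, ref_samples, windows, max_missing_site)
    out = focal[["chrom", "start", "end"]].copy()
    out["n_snps"] = np.maximum(focal["n_snps"], ref["n_snps"])
    out["pi_focal"] = focal["pi"]
    out["pi_ref"] = ref["pi"]
    out["fst"] = [
        weir_cockerham_fst(matrix, w, focal_samples, ref_samples, max_missing_site)
        for w in windows
    ]
    out["rod"] = [rod(f, r) for f, r in zip(focal["pi"], ref["pi"])]
    out["delta_d"] = [delta_tajima(f, r)
                      for f, r in zip(focal["tajima_d"], ref["tajima_d"])]
    return out


def window_stat_table(matrix: GenotypeMatrix, popmap: PopulationMap,
                      windows: Sequence[Window],
                      pairs: Sequence[tuple[str, str]] = (),
                      max_missing_site: float = DEFAULT_MAX_MISSING_SITE,
                      ) -> pd.DataFrame:
    """Tidy per-(window, group) table over all populations and pairs.

    Population rows carry the within-group columns; pair rows (group encoded
    as ``focal|reference``) carry fst/rod/delta_d.  Groups in ``pairs`` may be
    population labels or categories.
    """
    popmap.validate_against(matrix)
    frames = []
    for pop in popmap.populations:
        df = population_window_stats(matrix, popmap.samples_in(pop), windows,
                                     max_missing_site)
        df.insert(3, "group", pop)
        df.insert(4, "kind", "population")
        frames.append(df)
    for focal, reference in pairs:
        df = pair_window_stats(matrix, popmap.resolve_group(focal),
                               popmap.resolve_group(reference), windows,
                               max_missing_site)
        df.insert(3, "group", f"{focal}|{reference}")
        df.insert(4, "kind", "pair")
        frames.append(df)
    return pd.concat(frames, ignore_index=True, sort=False)
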