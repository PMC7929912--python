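"""Independent brute-force reference implementations used as test oracles.

These deliberately use naive enumeration / literal scalar formulas, not the
vectorised code paths of the package, so that agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def oracle_site_pi(alt: int, tot: int) -> float:
    """Mean pairwise difference by enumerating all allele pairs."""
    if tot < 2:
        return math.nan
    alleles = [1] * alt + [0] * (tot - alt)
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def _site_counts(column: np.ndarray) -> tuple[int, int, int, int]:
    """(alt alleles, total alleles, het individuals, non-missing individuals)."""
    alt = tot = het = n = 0
    for g in column:
        if g == MISSING:
            continue
        n += 1
        tot += 2
        alt += int(g)
        het += int(g == 1)
    return alt, tot, het, n


def oracle_window_pi(geno: np.ndarray, length: int) -> float:
    """Per-bp pi of a (samples x sites) genotype block."""
    total = 0.0
    for j in range(geno.shape[1]):
        alt, tot, _, _ = _site_counts(geno[:, j])
        if tot >= 2:
            total += oracle_site_pi(alt, tot)
    return total / length


def oracle_watterson(n_snps: int, n_alleles: int, length: int) -> float:
    if n_alleles < 2:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n_alleles))
    return n_snps / (a1 * length) if a1 else math.nan


def oracle_tajima_d(alt_counts, n: int) -> float:
    """Literal Tajima (1989) evaluation for a fixed allele count n."""
    seg = [j for j in alt_counts if 0 < j < n]
    s = len(seg)
    if s == 0 or n < 4:
        return math.nan
    pi_sum = sum(oracle_site_pi(j, n) for j in seg)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return (pi_sum - s / a1) / math.sqrt(var)


def oracle_he_ho(geno: np.ndarray) -> tuple[float, float]:
    """Mean unbiased He and observed Ho over variant sites of a block."""
    hes, hos = [], []
    for j in range(geno.shape[1]):
        alt, tot, het, n = _site_counts(geno[:, j])
        if tot < 2 or alt == 0 or alt == tot:
            continue
        p = alt / tot
        hes.append(2 * p * (1 - p) * tot / (tot - 1))
        hos.append(het / n)
    if not hes:
        return math.nan, math.nan
    return sum(hes) / len(hes), sum(hos) / len(hos)


def oracle_wc_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Weir & Cockerham (1984) theta-hat, scalar per-site transcription,
    ratio of summed components over sites."""
    num = den = 0.0
    any_site = False
    for j in range(geno_a.shape[1]):
        alt1, tot1, het1, n1 = _site_counts(geno_a[:, j])
        alt2, tot2, het2, n2 = _site_counts(geno_b[:, j])
        if n1 < 1 or n2 < 1:
            continue
        r = 2.0
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        p1, p2 = alt1 / tot1, alt2 / tot2
        h1, h2 = het1 / n1, het2 / n2
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num += a
        den += a + b + c
        any_site = True
    if not any_site or den == 0:
        return math.nan
    return num / den


def oracle_r2(g1, g2) -> float:
    """Squared Pearson correlation via explicit sum formulas."""
    pairs = [(float(a), float(b)) for a, b in zip(g1, g2)
             if a != MISSING and b != MISSING]
    n = len(pairs)
    if n < 3:
        return math.nan
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    syy = sum(y * y for y in ys)
    sxy = sum(x * y for x, y in pairs)
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx == 0 or vy == 0:
        return math.nan
    r = (n * sxy - sx * sy) / math.sqrt(vx * vy)
    return r * r
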