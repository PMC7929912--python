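"""DCMS composite selection scan.

Per-window statistics (F_ST, ROD, delta Tajima's D) are converted to
one-sided fractional-rank empirical P values, combined into a decorrelated
composite of multiple signals (DCMS) score with weights inverse to each
statistic's total absolute Spearman correlation, and calibrated against a
robust Gaussian null (median / 1.4826*MAD) to yield per-window P values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: statistic column -> tail in which selection evidence lies
DEFAULT_TAILS = {"fst": "upper", "rod": "upper", "delta_d": "lower"}

DEFAULT_THRESHOLD = 0.025


@dataclass
class GeneOverlapReport:
    """Genes overlapping significant windows, deduplicated across windows."""

    windows: pd.DataFrame
    genes: pd.DataFrame
    n_windows: int
    n_genes: int


def empirical_pvalues(values, tail: str = "upper") -> np.ndarray:
    """Fractional-rank empirical P values, p = rank / (n + 1).

    ``tail='upper'`` ranks descending (large values -> small p); ties get
    average ranks; NaN inputs yield NaN outputs and are excluded from n.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    n = int(ok.sum())
    if n == 0:
        return out
    x = -v[ok] if tail == "upper" else v[ok]
    out[ok] = sps.rankdata(x, method="average") / (n + 1.0)
    return out


def stat_correlation(stat_table) -> np.ndarray:
    """Pairwise-complete Spearman correlation matrix across windows.

    Accepts a (n_windows x m) array or DataFrame of raw statistic values.
    A statistic that is constant (or with too few complete pairs) gets zero
    off-diagonal entries, with a warning.
    """
    x = np.asarray(stat_table, dtype=float)
    if x.ndim != 2:
        raise ValueError("stat_table must be 2-D (windows x statistics)")
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 windows")
    if np.isfinite(x).all(axis=1).sum() < 10:
        warnings.warn("fewer than 10 windows with all statistics defined",
                      stacklevel=2)
    r = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            ok = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
            a, b = x[ok, i], x[ok, j]
            if ok.sum() < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"statistic {i} or {j} constant across windows; "
                    "correlation set to 0", stacklevel=2)
                rho = 0.0
            else:
                rho = sps.spearmanr(a, b).statistic
                if not np.isfinite(rho):
                    rho = 0.0
            r[i, j] = r[j, i] = rho
    return r


def dcms_scores(p_table, r: np.ndarray) -> np.ndarray:
    """DCMS_j = sum_i log10[(1-p_ij)/p_ij] / sum_k |r_ik|.

    Each statistic i is weighted by the inverse of its total absolute
    correlation (including |r_ii| = 1), so duplicated statistics share their
    weight and leave scores unchanged.  P values must lie strictly in (0, 1);
    windows with any missing P get a NaN score.
    """
    p = np.asarray(p_table, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    r = np.asarray(r, dtype=float)
    m = p.shape[1]
    if r.shape != (m, m):
        raise ValueError("correlation matrix shape does not match p_table")
    finite = np.isfinite(p)
    if ((p[finite] <= 0) | (p[finite] >= 1)).any():
        raise ValueError("P values must lie strictly in (0, 1)")
    weights = 1.0 / np.abs(r).sum(axis=1)
    terms = np.log10((1.0 - p) / p)
    scores = terms @ weights
    scores[~finite.all(axis=1)] = np.nan
    return scores


def dcms_pvalues(scores, robust: bool = True) -> np.ndarray:
    """Upper-tail P values of scores under a fitted Gaussian null.

    With ``robust=True`` the null location is the median and the scale is
    1.4826 * MAD; a zero MAD falls back to the standard deviation with a
    warning.
    """
    s = np.asarray(scores, dtype=float)
    ok = np.isfinite(s)
    if ok.sum() < 2:
        raise ValueError("need at least 2 defined scores")
    x = s[ok]
    if robust:
        loc = float(np.median(x))
        scale = 1.4826 * float(np.median(np.abs(x - loc)))
        if scale == 0:
            warnings.warn("MAD is zero; falling back to standard deviation",
                          stacklevel=2)
            scale = float(np.std(x))
    else:
        loc = float(np.mean(x))
        scale = float(np.std(x))
    out = np.full(s.shape, np.nan)
    if scale == 0:
        out[ok] = 0.5
        return out
    out[ok] = sps.norm.sf((x - loc) / scale)
    return out


def dcms_scan(pair_stats: pd.DataFrame,
              threshold: float = DEFAULT_THRESHOLD,
              tails: dict[str, str] | None = None,
              robust: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """Full scan over a pair-statistics table (fst / rod / delta_d columns).

    Returns the table with p_fst / p_rod / p_deltad / dcms / p_dcms /
    significant columns appended, plus the 3x3 Spearman matrix used for the
    weights.
    """
    tails = dict(DEFAULT_TAILS if tails is None else tails)
    stats_cols = list(tails)
    df = pair_stats.copy()
    p = np.column_stack([
        empirical_pvalues(df[c].to_numpy(), tails[c]) for c in stats_cols
    ])
    r = stat_correlation(df[stats_cols].to_numpy())
    scores = dcms_scores(p, r)
    pd_ = dcms_pvalues(scores, robust=robust)
    df["p_fst"] = p[:, stats_cols.index("fst")]
    df["p_rod"] = p[:, stats_cols.index("rod")]
    df["p_deltad"] = p[:, stats_cols.index("delta_d")]
    df["dcms"] = scores
    df["p_dcms"] = pd_
    df["significant"] = df["p_dcms"] < threshold
    return df, r


def significant_windows(results: pd.DataFrame,
                        threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Windows with p_dcms strictly below the threshold, sorted by p."""
    out = results[results["p_dcms"] < threshold]
    return out.sort_values("p_dcms", kind="stable").reset_index(drop=True)


def merge_adjacent_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge book-ended significant windows into maximal intervals."""
    merged = []
    w = windows.sort_values(["chrom", "start"])
    for _, row in w.iterrows():
        if merged and merged[-1][0] == row["chrom"] and merged[-1][2] >= row["start"]:
            merged[-1][2] = max(merged[-1][2], row["end"])
        else:
            merged.append([row["chrom"], row["start"], row["end"]])
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def genes_in_windows(windows: pd.DataFrame, genes: pd.DataFrame,
                     merge_adjacent: bool = False) -> GeneOverlapReport:
    """Genes whose half-open interval overlaps any window by >= 1 bp.

    Genes are counted once regardless of how many windows they touch; BED
    records on chromosomes absent from the window set are skipped with a
    warning.
    """
    win = windows[["chrom", "start", "end"]].copy()
    if merge_adjacent:
        win = merge_adjacent_windows(win)
    known = set(win["chrom"])
    unknown = sorted(set(genes["chrom"]) - known)
    if unknown and known:
        warnings.warn(f"skipping genes on unknown chromosomes: {unknown}",
                      stacklevel=2)
    hits = []
    for _, gene in genes.iterrows():
        if gene["chrom"] not in known:
            continue
        sub = win[win["chrom"] == gene["chrom"]]
        if ((gene["start"] < sub["end"]) & (gene["end"] > sub["start"])).any():
            hits.append(gene)
    genes_hit = (pd.DataFrame(hits).drop_duplicates(subset=["chrom", "start", "end", "name"])
                 if hits else pd.DataFrame(columns=genes.columns))
    return GeneOverlapReport(
        windows=win.reset_index(drop=True),
        genes=genes_hit.reset_index(drop=True),
        n_windows=len(win),
        n_genes=len(genes_hit),
    )
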