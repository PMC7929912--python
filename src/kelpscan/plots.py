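"""Optional presentation helpers; no numerical result depends on these."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def manhattan(df: pd.DataFrame, value_col: str, path: str | Path,
              threshold_col: str | None = None,
              threshold: float = 0.025) -> None:
    """Per-window Manhattan plot with alternating chromosome shading."""
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(df.groupby("chrom", sort=False)):
        x = offset + (sub["start"] + sub["end"]) / 2
        ax.scatter(x, sub[value_col], s=6,
                   color="#2a6f97" if i % 2 == 0 else "#61a5c2")
        if threshold_col is not None:
            sig = sub[threshold_col] < threshold
            ax.scatter(x[sig], sub.loc[sig, value_col], s=10, color="#d1495b")
        ticks.append(offset + sub["end"].max() / 2)
        labels.append(str(chrom))
        offset += sub["end"].max()
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_ylabel(value_col)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ld_curves(ld_table: pd.DataFrame, path: str | Path) -> None:
    """Mean r2 against distance for each group in a pipeline LD table."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, sub in ld_table.groupby("group", sort=False):
        sub = sub[pd.to_numeric(sub["bin_start"], errors="coerce").notna()]
        mid = (sub["bin_start"].astype(float) + sub["bin_end"].astype(float)) / 2
        ax.plot(mid / 1e3, sub["mean_r2"].astype(float), label=str(group))
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
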