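"""Thin plotting layer: Manhattan / QQ plots and LD-score diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd


def manhattan(table: pd.DataFrame, threshold: float | None = None, ax=None):
    """Manhattan plot of a GWAS table (chrom, pos, neglog10p)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks = []
    for i, (chrom, sub) in enumerate(table.groupby("chrom", sort=False)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["neglog10p"], s=4,
                   color="tab:blue" if i % 2 else "tab:gray")
        ticks.append((x.mean(), str(chrom)))
        offset = x.max()
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([c for _, c in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    return ax


def ld_vs_pvalue(ld: pd.DataFrame, table: pd.DataFrame, ax=None):
    """LD score against physical position, coloured by GWAS -log10(p)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    merged = ld.merge(table[["chrom", "pos", "neglog10p"]],
                      on=["chrom", "pos"], how="left")
    sc = ax.scatter(merged["pos"], merged["ld_score"], s=6,
                    c=merged["neglog10p"].fillna(0), cmap="viridis")
    ax.figure.colorbar(sc, ax=ax, label=r"$-\log_{10}(P)$")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("LD score")
    return ax


def qq(table: pd.DataFrame, ax=None):
    """QQ plot of GWAS p-values."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    p = np.sort(table["p"].to_numpy())
    exp = -np.log10((np.arange(p.size) + 0.5) / p.size)
    ax.scatter(exp, -np.log10(p), s=4)
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10}(P)$")
    ax.set_ylabel("observed $-\\log_{10}(P)$")
    return ax
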