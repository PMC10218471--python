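"""Small plotting helpers for scan and QC reports (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan(assoc: pd.DataFrame, path, thresholds=(5e-8, 1e-5)) -> None:
    """Manhattan plot of an association table (chrom, pos, p)."""
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(assoc.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(grp["p"]), s=4, color=["#30598c", "#8c9dc0"][i % 2])
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max()
    for thr, color in zip(thresholds, ("red", "blue")):
        ax.axhline(-np.log10(thr), color=color, lw=0.8, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq(pvals, path) -> None:
    """QQ plot of association p-values."""
    p = np.sort(np.asarray(pvals, dtype=float))
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(exp, -np.log10(p), s=4, color="#30598c")
    lim = max(exp.max(), -np.log10(p[0])) if p.size else 1
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def depth_profile(profile: pd.DataFrame, path) -> None:
    """Mean capture depth vs distance from the target locus."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile["offset"], profile["mean_depth"], marker="o", ms=3)
    ax.set_xlabel("distance from target (bp)")
    ax.set_ylabel("mean depth (X)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def gap_histogram(gaps, path) -> None:
    """Histogram of adjacent panel-locus spacing."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(np.asarray(gaps) / 1e3, bins=40, color="#30598c")
    ax.set_xlabel("adjacent spacing (kb)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
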