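"""Data-faithful matplotlib figures for pipeline QC and enrichment output."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def count_histogram(values, sample_label: str, path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    vals = np.asarray(list(values), dtype=float)
    ax.hist(np.log10(vals + 1), bins=50, color="steelblue")
    ax.set_xlabel("log10(raw reads + 1)")
    ax.set_ylabel("reporters")
    ax.set_title(f"{sample_label}: per-reporter read counts")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def correlation_heatmap(corr: pd.DataFrame, path: str) -> None:
    fig, ax = plt.subplots(figsize=(4 + 0.3 * len(corr), 3.5 + 0.3 * len(corr)))
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr.index)), corr.index)
    for i in range(len(corr.index)):
        for j in range(len(corr.columns)):
            ax.text(j, i, f"{corr.iat[i, j]:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pairwise_scatter(te: pd.DataFrame, path: str) -> None:
    cols = list(te.columns)
    n = len(cols)
    fig, axes = plt.subplots(n, n, figsize=(2.2 * n, 2.2 * n), squeeze=False)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            ax = axes[i][j]
            if i == j:
                ax.hist(np.log2(te[ci].replace(0, np.nan).dropna()), bins=30, color="grey")
            else:
                ax.scatter(np.log2(te[cj]), np.log2(te[ci]), s=2, alpha=0.4)
            if i == n - 1:
                ax.set_xlabel(cj, fontsize=7)
            if j == 0:
                ax.set_ylabel(ci, fontsize=7)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def te_histogram(mean_te: pd.Series, groups: dict[str, list[str]], path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    logte = np.log2(mean_te.replace(0, np.nan).dropna())
    ax.hist(logte, bins=60, color="lightgrey", label="all")
    colors = {"repressed": "darkorange", "activated": "steelblue"}
    for gname, members in groups.items():
        sub = logte.loc[[m for m in members if m in logte.index]]
        ax.hist(sub, bins=60, color=colors.get(gname, None), label=gname, alpha=0.8)
    ax.set_xlabel("log2 mean TE")
    ax.set_ylabel("reporters")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def te_scatter(
    te1: pd.Series, te2: pd.Series, groups: dict[str, list[str]], labels: tuple[str, str], path: str
) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    common = te1.index.intersection(te2.index)
    ax.scatter(np.log2(te1[common]), np.log2(te2[common]), s=3, c="lightgrey")
    palette = {
        "both_low": "darkorange",
        "both_high": "steelblue",
        "sample1_high": "seagreen",
        "sample2_high": "orchid",
    }
    for gname, members in groups.items():
        members = [m for m in members if m in common]
        ax.scatter(
            np.log2(te1[members]), np.log2(te2[members]),
            s=4, c=palette.get(gname), label=gname,
        )
    ax.set_xlabel(f"log2 mean TE {labels[0]}")
    ax.set_ylabel(f"log2 mean TE {labels[1]}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def enrichment_plot(records: pd.DataFrame, group_name: str, path: str, top: int = 20) -> None:
    """Bar plot of the most significant k-mers by adjusted p, signed by enrichment."""
    df = records.sort_values("adjusted_p").head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(df) + 1.5))
    colors = ["steelblue" if v >= 0 else "darkorange" for v in df["log2_enrichment"]]
    ax.barh(df["kmer"], df["log2_enrichment"], color=colors)
    ax.set_xlabel("log2 enrichment (group vs background)")
    ax.set_title(group_name)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
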