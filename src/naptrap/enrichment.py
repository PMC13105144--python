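"""Replicate-correlation QC and group-wise k-mer enrichment.

After filtering, reporters are ranked by mean TE. In single-sample mode the
bottom and top ``rnum`` fractions form the *repressed* and *activated*
groups; in two-sample mode the per-sample top/bottom fractions are
intersected into four quadrant groups (both-high, both-low, high in one
sample only). For every k-mer of the configured length we compare its
presence frequency (a reporter counts once however many times the k-mer
occurs) in a group against the background of all passing reporters, report a
pseudocounted log2 enrichment, a hypergeometric tail p-value (the group is a
draw without replacement from the background) and a Benjamini-Hochberg
adjusted p across all k-mers of the group.

The enrichment statistic is this package's own definition: presence/absence
frequencies with a hypergeometric test is the simplest model under which the
group is exchangeable with the background.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_DNA = "ACGT"


@dataclass(frozen=True)
class EnrichmentConfig:
    rnum: float = 0.1        # fraction of passing reporters per group
    klen: int = 5            # k-mer length, nt
    pseudocount: float = 0.5 # added to presence counts in the log2 enrichment
    rna_alphabet: bool = False  # report k-mers with U instead of T

    def __post_init__(self):
        if not (0 < self.rnum <= 0.5):
            raise ValueError("rnum must be in (0, 0.5]")
        if self.klen < 1:
            raise ValueError("klen must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def group_size(self, n_passing: int) -> int:
        g = math.floor(self.rnum * n_passing)
        if g < 1:
            raise ValueError(
                f"rnum {self.rnum} over {n_passing} reporters gives an empty group"
            )
        return g


@dataclass
class ReporterGroups:
    """Named, pairwise-disjoint reporter groups plus the defining mode."""

    groups: dict[str, list[str]]
    mode: str  # "single" | "two_sample"

    def __getitem__(self, name: str) -> list[str]:
        return self.groups[name]

    def items(self):
        return self.groups.items()


def replicate_correlation(
    te: pd.DataFrame,
    out_dir: str | os.PathLike | None = None,
    fig_format: str = "pdf",
    prefix: str = "replicates",
) -> pd.DataFrame:
    """Pearson r between replicate TE columns (complete cases only).

    Returns the symmetric unit-diagonal correlation matrix; writes a heatmap
    and a pairwise scatter grid when *out_dir* is given.
    """
    if te.shape[1] < 2:
        raise ValueError("replicate correlation needs >= 2 replicates")
    complete = te.dropna()
    corr = complete.corr(method="pearson")
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        from . import viz

        viz.correlation_heatmap(corr, os.path.join(out_dir, f"{prefix}_heatmap.{fig_format}"))
        viz.pairwise_scatter(complete, os.path.join(out_dir, f"{prefix}_scatter.{fig_format}"))
    return corr


def _ranked(mean_te: pd.Series) -> list[str]:
    """Reporter names sorted by (TE, name): deterministic under ties."""
    s = mean_te.dropna()
    return [name for name, _ in sorted(s.items(), key=lambda kv: (kv[1], kv[0]))]


def define_groups(
    mean_te_1: pd.Series,
    mean_te_2: pd.Series | None = None,
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> ReporterGroups:
    """Rank-based TE groups (invariant to monotone transforms of TE).

    Single sample: bottom/top ``rnum`` fraction -> repressed/activated.
    Two samples: per-sample bottom/top fractions intersected into quadrants
    (intersections may be smaller than the per-sample fraction, or empty).
    """
    if mean_te_2 is None:
        order = _ranked(mean_te_1)
        g = cfg.group_size(len(order))
        return ReporterGroups(
            {"repressed": sorted(order[:g]), "activated": sorted(order[-g:])},
            "single",
        )
    common = mean_te_1.dropna().index.intersection(mean_te_2.dropna().index)
    o1 = _ranked(mean_te_1[common])
    o2 = _ranked(mean_te_2[common])
    g = cfg.group_size(len(common))
    low1, high1 = set(o1[:g]), set(o1[-g:])
    low2, high2 = set(o2[:g]), set(o2[-g:])
    return ReporterGroups(
        {
            "both_low": sorted(low1 & low2),
            "both_high": sorted(high1 & high2),
            "sample1_high": sorted(high1 & low2),
            "sample2_high": sorted(low1 & high2),
        },
        "two_sample",
    )


def kmer_presence(sequences: Mapping[str, str], klen: int) -> dict[str, frozenset[str]]:
    """Per-reporter set of distinct k-mers present in its insert."""
    out = {}
    for name, seq in sequences.items():
        out[name] = frozenset(seq[i : i + klen] for i in range(len(seq) - klen + 1))
    return out


def kmer_enrichment(
    groups: ReporterGroups | Mapping[str, Sequence[str]],
    background: Mapping[str, str],
    cfg: EnrichmentConfig = EnrichmentConfig(),
    out_dir: str | os.PathLike | None = None,
    fig_format: str = "pdf",
) -> dict[str, pd.DataFrame]:
    """Presence-based k-mer enrichment of each group against the background.

    Background = all passing reporters (group members included). Returns one
    table per group over all 4^klen k-mers with presence counts, frequencies,
    pseudocounted log2 enrichment, hypergeometric tail p-value and BH-adjusted
    p. Writes per-group CSV tables and bar plots when *out_dir* is given.
    """
    if isinstance(groups, ReporterGroups):
        group_map = groups.groups
    else:
        group_map = dict(groups)
    shortest = min((len(s) for s in background.values()), default=0)
    if cfg.klen > shortest:
        raise ValueError(
            f"klen {cfg.klen} exceeds the shortest insert length {shortest}"
        )
    kmers = ["".join(p) for p in product(_DNA, repeat=cfg.klen)]
    presence = kmer_presence(background, cfg.klen)
    bg_size = len(background)
    bg_present = np.zeros(len(kmers), dtype=np.int64)
    kidx = {k: i for i, k in enumerate(kmers)}
    for pset in presence.values():
        for k in pset:
            bg_present[kidx[k]] += 1

    pc = cfg.pseudocount
    results: dict[str, pd.DataFrame] = {}
    for gname, members in group_map.items():
        unknown = [m for m in members if m not in background]
        if unknown:
            raise KeyError(f"group {gname!r} members not in background: {unknown[:5]}")
        g_size = len(members)
        g_present = np.zeros(len(kmers), dtype=np.int64)
        for m in members:
            for k in presence[m]:
                g_present[kidx[k]] += 1
        freq_g = g_present / g_size if g_size else np.zeros(len(kmers))
        freq_b = bg_present / bg_size
        # pc = 0 gives -inf for k-mers absent from one side and NaN (inf - inf)
        # for k-mers absent from both; both are the documented degenerate values
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_enr = np.log2((g_present + pc) / (g_size + 2 * pc)) - np.log2(
                (bg_present + pc) / (bg_size + 2 * pc)
            )
        # P(X >= g_present) with X ~ Hypergeom(N=bg_size, K=bg_present, n=g_size)
        pvals = stats.hypergeom.sf(g_present - 1, bg_size, bg_present, g_size)
        adj = stats.false_discovery_control(pvals, method="bh") if len(pvals) else pvals
        names = kmers
        if cfg.rna_alphabet:
            names = [k.replace("T", "U") for k in kmers]
        df = pd.DataFrame(
            {
                "kmer": names,
                "group_present": g_present,
                "bg_present": bg_present,
                "frequency_group": freq_g,
                "frequency_background": freq_b,
                "log2_enrichment": log2_enr,
                "p_value": pvals,
                "adjusted_p": adj,
            }
        )
        results[gname] = df
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            df.to_csv(os.path.join(out_dir, f"kmer_enrichment_{gname}.csv"), index=False)
            from . import viz

            viz.enrichment_plot(
                df, gname, os.path.join(out_dir, f"kmer_enrichment_{gname}.{fig_format}")
            )
    return results
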