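"""From raw counts to normalized counts and translation values.

Translation efficiency (TE) of a reporter is the ratio of its normalized
abundance in the ribosome pulldown fraction to the paired input fraction.
Normalization uses the spike-in ladder — synthetic reporters added at known
relative amounts (1 : 5 : 25 : 50 : 125 by default) during RNA extraction —
via a median-of-ratios scale factor per sample, which is robust to a single
spike-in dropping out and cancels any sample-wide depth difference. A
total-count (counts-per-million over reporters, spike-ins excluded) fallback
is provided for runs without spike-ins.

Reporter filtering follows the assay's stated mechanism for taming ratio
noise: a reporter enters an analysis only if its RAW count reaches the
selector's floor in EVERY input replicate of every selected condition.
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import ReporterLibrary


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: a (condition, fraction, replicate) cell."""

    label: str
    condition: str
    fraction: str  # "input" | "pulldown"
    replicate: int
    barcode: str | None = None

    def __post_init__(self):
        if self.fraction not in ("input", "pulldown"):
            raise ValueError(f"fraction must be input/pulldown, got {self.fraction!r}")


@dataclass
class ExperimentDesign:
    """Sample sheet plus the input<->pulldown replicate pairing."""

    samples: list[SampleInfo]
    explicit_pairs: dict[str, str] = field(default_factory=dict)  # pulldown label -> input label

    def __post_init__(self):
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate sample labels in design")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    def inputs(self, condition: str) -> list[SampleInfo]:
        return [s for s in self.samples if s.condition == condition and s.fraction == "input"]

    def pairs(self, condition: str) -> list[tuple[SampleInfo, SampleInfo]]:
        """(input, pulldown) pairs; replicate i pairs with replicate i unless
        overridden in ``explicit_pairs``."""
        ins = {s.replicate: s for s in self.inputs(condition)}
        by_label = {s.label: s for s in self.samples}
        out = []
        for pd_ in (s for s in self.samples if s.condition == condition and s.fraction == "pulldown"):
            if pd_.label in self.explicit_pairs:
                out.append((by_label[self.explicit_pairs[pd_.label]], pd_))
            elif pd_.replicate in ins:
                out.append((ins[pd_.replicate], pd_))
            else:
                raise ValueError(
                    f"pulldown sample {pd_.label!r} (replicate {pd_.replicate}) has no "
                    "paired input replicate"
                )
        return out


@dataclass(frozen=True)
class SpikeinLadder:
    """Expected relative amounts of each spike-in (dimensionless ladder)."""

    amounts: Mapping[str, float]  # spike-in name -> relative amount

    def __post_init__(self):
        if not self.amounts:
            raise ValueError("ladder is empty")
        if any(a <= 0 for a in self.amounts.values()):
            raise ValueError("ladder amounts must be strictly positive")

    def validate_against(self, lib: ReporterLibrary) -> None:
        for name in self.amounts:
            if name not in lib or not lib.is_spikein(name):
                raise ValueError(f"ladder member {name!r} is not a spike-in in the library")


@dataclass(frozen=True)
class Selector:
    """Named analysis subset: conditions + a raw-count floor on input replicates."""

    name: str
    conditions: tuple[str, ...]
    min_input_reads: int = 100

    def __post_init__(self):
        if not self.conditions:
            raise ValueError(f"selector {self.name!r} selects no conditions")


def spikein_factors(
    counts: Mapping[str, Mapping[str, int]], ladder: SpikeinLadder
) -> dict[str, float]:
    """Per-sample scale factor: median over ladder members of count/amount.

    Zero-count ladder members are dropped (dropout robustness); a sample in
    which every ladder member is zero is a hard error — fall back to
    total-count normalization instead.
    """
    factors = {}
    for sample, table in counts.items():
        ratios = [
            table.get(name, 0) / amount
            for name, amount in ladder.amounts.items()
            if table.get(name, 0) > 0
        ]
        if not ratios:
            raise ValueError(
                f"sample {sample!r}: all spike-in counts are zero; spike-in "
                "normalization is impossible — use total-count (CPM) normalization"
            )
        factors[sample] = float(median(ratios))
    return factors


def total_count_factors(
    counts: Mapping[str, Mapping[str, int]], lib: ReporterLibrary | None = None
) -> dict[str, float]:
    """CPM fallback: factor = (reporter-count sum, spike-ins excluded) / 1e6."""
    factors = {}
    for sample, table in counts.items():
        total = sum(
            c
            for name, c in table.items()
            if not (lib.is_spikein(name) if lib is not None and name in lib else name.endswith("#spikein"))
        )
        if total == 0:
            raise ValueError(f"sample {sample!r} has zero reporter reads")
        factors[sample] = total / 1e6
    return factors


def normalize(
    counts: Mapping[str, Mapping[str, int]], factors: Mapping[str, float]
) -> pd.DataFrame:
    """Normalized count = raw count / sample factor. Rows reporters, cols samples."""
    raw = pd.DataFrame(counts).fillna(0)
    missing = [c for c in raw.columns if c not in factors]
    if missing:
        raise KeyError(f"no factor for samples {missing}")
    if any(factors[c] <= 0 for c in raw.columns):
        raise ValueError("factors must be positive")
    return raw / pd.Series(factors)[raw.columns]


@dataclass
class TeTable:
    """Raw counts, normalized counts, per-replicate TE and per-condition mean TE."""

    raw: pd.DataFrame          # reporters x samples
    normalized: pd.DataFrame   # reporters x samples
    te: pd.DataFrame           # reporters x "<condition>:<replicate>"
    mean_te: pd.DataFrame      # reporters x condition
    te_function: str           # "ratio" | "log2_ratio"
    pass_flags: dict[str, pd.Series] = field(default_factory=dict)  # selector name -> bool per reporter

    def filtered(self, selector_name: str) -> "TeTable":
        mask = self.pass_flags[selector_name]
        keep = mask[mask].index
        return TeTable(
            self.raw.loc[self.raw.index.intersection(keep)],
            self.normalized.loc[self.normalized.index.intersection(keep)],
            self.te.loc[self.te.index.intersection(keep)],
            self.mean_te.loc[self.mean_te.index.intersection(keep)],
            self.te_function,
            {selector_name: mask[mask]},
        )


def translation(
    counts: Mapping[str, Mapping[str, int]],
    design: ExperimentDesign,
    factors: Mapping[str, float],
    lib: ReporterLibrary | None = None,
    te_function: str = "ratio",
) -> TeTable:
    """Compute per-replicate TE = normalized pulldown / normalized input.

    ``ratio`` mode averages per-replicate ratios arithmetically per condition;
    ``log2_ratio`` mode reports log2 ratios and averages in log space. A
    reporter whose normalized input is 0 gets a missing TE (NaN) for that
    replicate, never 0 or infinity; spike-ins are dropped from TE output.
    """
    if te_function not in ("ratio", "log2_ratio"):
        raise ValueError(f"unknown te_function {te_function!r}")
    raw = pd.DataFrame(counts).fillna(0).astype(float)
    norm = normalize(counts, factors)
    if lib is not None:
        reporters = [r.name for r in lib.reporters if r.name in norm.index]
        norm_rep = norm.loc[reporters]
    else:
        norm_rep = norm.loc[[n for n in norm.index if not n.endswith("#spikein")]]

    te_cols = {}
    by_cond: dict[str, list[str]] = {}
    for cond in design.conditions:
        for inp, pld in design.pairs(cond):
            col = f"{cond}:{inp.replicate}"
            num = norm_rep[pld.label]
            den = norm_rep[inp.label].replace(0, np.nan)
            ratio = num / den
            te_cols[col] = np.log2(ratio.where(ratio > 0)) if te_function == "log2_ratio" else ratio
            by_cond.setdefault(cond, []).append(col)
    te = pd.DataFrame(te_cols)
    mean_te = pd.DataFrame({cond: te[cols].mean(axis=1) for cond, cols in by_cond.items()})
    return TeTable(raw, norm, te, mean_te, te_function)


def apply_selector(
    te_table: TeTable,
    design: ExperimentDesign,
    selector: Selector,
) -> TeTable:
    """Flag reporters whose raw count >= floor in every input replicate of
    every selected condition; returns the same table with the flag recorded."""
    for cond in selector.conditions:
        if cond not in design.conditions:
            raise ValueError(
                f"selector {selector.name!r} references unknown condition {cond!r}"
            )
    input_labels = [
        s.label for cond in selector.conditions for s in design.inputs(cond)
    ]
    if not input_labels:
        raise ValueError(f"selector {selector.name!r} selects no input samples")
    raw_inputs = te_table.raw.loc[te_table.te.index, input_labels]
    mask = (raw_inputs >= selector.min_input_reads).all(axis=1)
    te_table.pass_flags[selector.name] = mask
    return te_table


def build_tables(
    counts: Mapping[str, Mapping[str, int]],
    design: ExperimentDesign,
    lib: ReporterLibrary,
    selectors: Sequence[Selector],
    out_dir: str | os.PathLike,
    db_path: str | os.PathLike | None = None,
    ladder: SpikeinLadder | None = None,
    te_function: str = "ratio",
) -> TeTable:
    """Run normalization + TE and persist the full table set.

    Writes CSV exports (raw counts, normalized counts, translation, average
    translation; per selector both unfiltered and filtered), each row carrying
    the insert sequence, plus a single-file SQLite store when *db_path* is
    given. Reporter rows are sorted lexicographically so re-runs are
    byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    if ladder is not None:
        ladder.validate_against(lib)
        factors = spikein_factors(counts, ladder)
    else:
        factors = total_count_factors(counts, lib)
    tab = translation(counts, design, factors, lib, te_function)
    for sel in selectors:
        apply_selector(tab, design, sel)

    seqs = pd.Series({r.name: r.insert_seq for r in lib}, name="insert_seq")

    def export(df: pd.DataFrame, name: str) -> None:
        out = df.sort_index().copy()
        out.insert(0, "insert_seq", seqs.reindex(out.index))
        out.to_csv(os.path.join(out_dir, f"{name}.csv"), index_label="reporter")

    export(tab.raw, "raw_counts")
    export(tab.normalized, "normalized_counts")
    export(tab.te, "translation")
    export(tab.mean_te, "average_translation")
    for sel in selectors:
        filt = tab.filtered(sel.name)
        export(filt.te, f"{sel.name}_filtered_translation")
        export(filt.mean_te, f"{sel.name}_filtered_average_translation")

    if db_path is not None:
        db_path = os.fspath(db_path)
        if not os.path.isabs(db_path):
            raise ValueError(
                f"database path must be absolute, got {db_path!r}"
            )
        con = sqlite3.connect(db_path)
        try:
            seqs.sort_index().to_frame().to_sql("library", con, if_exists="replace", index_label="reporter")
            tab.raw.sort_index().to_sql("raw_counts", con, if_exists="replace", index_label="reporter")
            tab.normalized.sort_index().to_sql("normalized_counts", con, if_exists="replace", index_label="reporter")
            tab.te.sort_index().to_sql("translation", con, if_exists="replace", index_label="reporter")
            tab.mean_te.sort_index().to_sql("average_translation", con, if_exists="replace", index_label="reporter")
            flags = pd.DataFrame(tab.pass_flags).sort_index()
            flags.to_sql("selector_pass", con, if_exists="replace", index_label="reporter")
            con.commit()
        finally:
            con.close()
    return tab
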