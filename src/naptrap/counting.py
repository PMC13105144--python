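"""UMI-aware counting of aligned reporter reads.

A read contributes to a reporter's count iff it is a mapped, primary,
non-supplementary alignment, its CIGAR match-base total (M and = operations)
reaches ``min_matches`` and its NM-tag edit distance does not exceed
``max_edit_distance``. Among contributing reads each distinct
(reporter, UMI) pair counts exactly once — the UMI rides in the read name
after the final ``#`` — which removes PCR duplicates.

Counting is order-invariant and idempotent under record duplication by
construction (it builds a set of pairs).
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .library import ReporterLibrary

# CIGAR ops counted as aligned match bases: M (0) and = (7); X excluded.
_MATCH_OPS = frozenset((0, 7))


@dataclass(frozen=True)
class CountFilter:
    """Alignment inclusion filter: CIGAR match floor and NM ceiling."""

    min_matches: int = 0
    max_edit_distance: int | None = None

    def __post_init__(self):
        if self.min_matches < 0:
            raise ValueError("min_matches must be >= 0")
        if self.max_edit_distance is not None and self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be >= 0")


@dataclass
class CountTable:
    """Per-sample deduplicated counts plus filter provenance."""

    sample_label: str
    counts: dict[str, int]
    filter: CountFilter
    reads_seen: int = 0
    reads_passing: int = 0

    @property
    def umis_counted(self) -> int:
        return sum(self.counts.values())


def _umi_from_name(name: str) -> str:
    if "#" not in name:
        raise ValueError(f"read name {name!r} carries no '#<UMI>' suffix")
    return name.rsplit("#", 1)[1]


def _iter_normalized(alignments):
    """Yield (read_name, reference, match_bases, nm_or_None) for usable records.

    Accepts a SAM/BAM path (``.sam``, ``.bam``, ``.sam.zst``), an iterable of
    pysam.AlignedSegment, or an iterable of pre-normalized 4-tuples.
    """
    if isinstance(alignments, (str, os.PathLike)):
        import pysam

        path = os.fspath(alignments)
        if path.endswith(".zst"):
            from .io import open_text

            with open_text(path) as src, tempfile.NamedTemporaryFile(
                "w", suffix=".sam", delete=False
            ) as tmp:
                for line in src:
                    tmp.write(line)
                tmp_path = tmp.name
            try:
                yield from _iter_normalized_pysam(pysam.AlignmentFile(tmp_path, check_sq=False))
            finally:
                os.unlink(tmp_path)
            return
        yield from _iter_normalized_pysam(pysam.AlignmentFile(path, check_sq=False))
        return

    alignments = iter(alignments)
    try:
        first = next(alignments)
    except StopIteration:
        return
    if isinstance(first, tuple):
        yield first
        yield from alignments
        return
    import itertools

    yield from _iter_normalized_pysam(itertools.chain([first], alignments))


def _iter_normalized_pysam(records):
    for aln in records:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        matches = sum(n for op, n in (aln.cigartuples or ()) if op in _MATCH_OPS)
        nm = aln.get_tag("NM") if aln.has_tag("NM") else None
        yield (aln.query_name, aln.reference_name, matches, nm)
    if hasattr(records, "close"):
        records.close()


def count_sample(
    alignments,
    lib: ReporterLibrary | None = None,
    filter: CountFilter = CountFilter(),
    sample_label: str = "",
) -> CountTable:
    """Count UMI-deduplicated reads per reporter for one sample.

    With a library supplied, every library record appears in the result (zero
    counts included) and alignments to unknown references are rejected.
    """
    seen: dict[str, set[str]] = {}
    reads_seen = 0
    reads_passing = 0
    d1 = filter.max_edit_distance
    for name, ref, matches, nm in _iter_normalized(alignments):
        reads_seen += 1
        if lib is not None and ref not in lib:
            raise ValueError(f"alignment reference {ref!r} is not in the library")
        if matches < filter.min_matches:
            continue
        if d1 is not None:
            if nm is None:
                raise ValueError(
                    f"alignment of {name!r} lacks an NM tag; cannot apply the "
                    "edit-distance filter"
                )
            if nm > d1:
                continue
        reads_passing += 1
        seen.setdefault(ref, set()).add(_umi_from_name(name))

    counts = {ref: len(umis) for ref, umis in seen.items()}
    if lib is not None:
        counts = {rec.name: counts.get(rec.name, 0) for rec in lib}
    return CountTable(sample_label, counts, filter, reads_seen, reads_passing)


def merge_counts(
    tables: Sequence[CountTable], lib: ReporterLibrary | None = None
) -> dict[str, dict[str, int]]:
    """Combine per-sample tables into one {sample: {reporter: count}} mapping.

    With a library, every record appears in every sample (absent -> 0); the
    mapping is key-sorted so serialization is canonical regardless of input
    order.
    """
    labels = [t.sample_label for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {sorted(labels)}")
    out: dict[str, dict[str, int]] = {}
    for t in sorted(tables, key=lambda t: t.sample_label):
        counts = dict(t.counts)
        if lib is not None:
            counts = {rec.name: counts.get(rec.name, 0) for rec in lib}
        out[t.sample_label] = dict(sorted(counts.items()))
    return out


def write_count_file(merged: Mapping[str, Mapping[str, int]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(merged, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_count_file(path: str | os.PathLike) -> dict[str, dict[str, int]]:
    with open(path) as fh:
        return json.load(fh)


@dataclass
class CutoffTable:
    """Reporters passing each minimum-count threshold, for one sample."""

    sample_label: str
    thresholds: list[int]
    reporters_passing: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "reporters_passing": self.reporters_passing}
        )


def _is_spikein_name(name: str, lib: ReporterLibrary | None) -> bool:
    if lib is not None and name in lib:
        return lib.is_spikein(name)
    return name.endswith("#spikein")


def read_cutoff(
    counts: Mapping[str, Mapping[str, int]] | str | os.PathLike,
    thresholds: Sequence[int] = (1, 10, 50, 100, 200, 500, 1000),
    samples: Sequence[str] | None = None,
    lib: ReporterLibrary | None = None,
    out_dir: str | os.PathLike | None = None,
    fig_format: str = "pdf",
    strict: bool = False,
) -> dict[str, CutoffTable]:
    """Tabulate reporters meeting each minimum read-count threshold per sample.

    Spike-ins are excluded. The comparison is inclusive (count >= T) unless
    ``strict`` is set (count > T). When *out_dir* is given a
    ``Cutoff_vs_Count_table_<sample>.csv`` and a count histogram are written
    per sample.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if isinstance(counts, (str, os.PathLike)):
        counts = read_count_file(counts)
    if samples is None:
        samples = sorted(counts)
    missing = [s for s in samples if s not in counts]
    if missing:
        raise KeyError(
            f"samples {missing} not in count file; available: {sorted(counts)}"
        )
    thresholds = sorted(thresholds)
    out: dict[str, CutoffTable] = {}
    for s in samples:
        vals = [c for name, c in counts[s].items() if not _is_spikein_name(name, lib)]
        passing = [
            sum(1 for v in vals if (v > t if strict else v >= t)) for t in thresholds
        ]
        out[s] = CutoffTable(s, list(thresholds), passing)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        from . import viz

        for s, table in out.items():
            table.to_frame().to_csv(
                os.path.join(out_dir, f"Cutoff_vs_Count_table_{s}.csv"), index=False
            )
            vals = [c for name, c in counts[s].items() if not _is_spikein_name(name, lib)]
            viz.count_histogram(
                vals, s, os.path.join(out_dir, f"count_histogram_{s}.{fig_format}")
            )
    return out
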