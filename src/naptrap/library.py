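"""Reporter library model.

A NaP-TRAP reporter library is distributed as a FASTA file in which every
record name carries a ``#reporter`` or ``#spikein`` suffix; the suffix is how
the rest of the pipeline tells experimental reporters apart from the
spike-in normalization controls. The suffix is part of the record name
everywhere (it is what alignment reference names look like); use
:meth:`ReporterRecord.display_name` for human-facing tables.

Also provides a dependency-free exact/near-exact read assigner that can stand
in for an external aligner on substitution-only reads, emitting SAM that the
counting module consumes identically to aligner output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .io import FastqRecord, open_text

REPORTER_SUFFIX = "#reporter"
SPIKEIN_SUFFIX = "#spikein"

_ENCODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT", start=1):
    _ENCODE[_b] = _i
# 'N' stays 0 on the read side; library-side N is remapped to 255 below so it
# never equals any read base (N never counts as a match).


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ReporterRecord:
    """One library entry: full header-token name, insert sequence, kind."""

    name: str
    insert_seq: str
    kind: str  # "reporter" | "spikein"

    def __post_init__(self):
        if not self.insert_seq:
            raise ValueError(f"record {self.name!r} has an empty sequence")
        if set(self.insert_seq) - set("ACGTN"):
            bad = sorted(set(self.insert_seq) - set("ACGTN"))
            raise ValueError(f"record {self.name!r} contains non-ACGTN characters {bad}")
        expected = "spikein" if self.name.endswith(SPIKEIN_SUFFIX) else "reporter"
        if self.kind != expected:
            raise ValueError(f"record {self.name!r}: kind {self.kind!r} contradicts name suffix")

    @property
    def display_name(self) -> str:
        """Name with the classification suffix stripped, for report tables."""
        return self.name.rsplit("#", 1)[0]


@dataclass
class ReporterLibrary:
    """Ordered, uniquely named collection of reporters and spike-ins."""

    records: list[ReporterRecord]
    truncated_to: int | None = None
    _by_name: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate record names: {dupes}")
        for r in self.records:
            if r.kind == "reporter" and "spikein" in r.name:
                raise ValueError(
                    f"reporter {r.name!r} contains the string 'spikein' in its name; "
                    "it would be misclassified as a spike-in downstream"
                )
        self._by_name = {r.name: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReporterRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> ReporterRecord:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def reporters(self) -> list[ReporterRecord]:
        return [r for r in self.records if r.kind == "reporter"]

    @property
    def spikeins(self) -> list[ReporterRecord]:
        return [r for r in self.records if r.kind == "spikein"]

    def is_spikein(self, name: str) -> bool:
        return self._by_name[name].kind == "spikein"


def parse_library(fasta_source: str | os.PathLike) -> ReporterLibrary:
    """Parse a reporter-library FASTA.

    Every header must end with ``#reporter`` or ``#spikein``; the record name
    is the header token up to the first whitespace, suffix included.
    """
    records = []
    with open_text(fasta_source) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name = rec.id
            if name.endswith(SPIKEIN_SUFFIX):
                kind = "spikein"
            elif name.endswith(REPORTER_SUFFIX):
                kind = "reporter"
            else:
                raise ValueError(
                    f"FASTA record {name!r} lacks a '#reporter' or '#spikein' suffix"
                )
            records.append(ReporterRecord(name, str(rec.seq).upper(), kind))
    return ReporterLibrary(records)


def write_library(lib: ReporterLibrary, path: str | os.PathLike) -> None:
    """Write the library as single-line-sequence FASTA (bowtie2-build ready)."""
    with open_text(path, "wt") as fh:
        for rec in lib:
            fh.write(f">{rec.name}\n{rec.insert_seq}\n")


def truncate_inserts(lib: ReporterLibrary, read_len: int) -> tuple[ReporterLibrary, list[list[str]]]:
    """Truncate every insert to its 5' prefix of ``read_len`` nt.

    Returns the truncated library and a collision report: groups of record
    names whose truncated sequences became identical (an ambiguous-mapping
    risk for tiled libraries with small steps).
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    new = [replace(r, insert_seq=r.insert_seq[:read_len]) for r in lib]
    out = ReporterLibrary(new, truncated_to=read_len)
    groups: dict[str, list[str]] = {}
    for r in out:
        groups.setdefault(r.insert_seq, []).append(r.name)
    collisions = sorted((sorted(v) for v in groups.values() if len(v) > 1))
    return out, collisions


@dataclass(frozen=True)
class ReadAssignment:
    read_name: str
    reference: str | None  # None = unassigned
    mismatches: int | None

    @property
    def assigned(self) -> bool:
        return self.reference is not None


def assign_reads_exact(
    reads: Iterable[FastqRecord | tuple[str, str]],
    lib: ReporterLibrary,
    max_mismatch: int = 0,
) -> list[ReadAssignment]:
    """Assign reads to library records by Hamming distance on the read prefix.

    A read is assigned iff exactly one record's insert (possibly truncated)
    matches the read prefix with <= ``max_mismatch`` substitutions, comparing
    over min(read length, insert length) bases; ``N`` in the library never
    counts as a match. Two or more records within budget -> unassigned.

    Substitution-only by construction: indel-containing reads are an external
    aligner's job.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    recs = list(lib)
    seqs = [r.insert_seq for r in recs]
    if len(set(seqs)) != len(seqs):
        raise ValueError("library inserts are not pairwise distinct; truncate with care")

    norm_reads: list[tuple[str, str]] = []
    for rd in reads:
        if isinstance(rd, FastqRecord):
            norm_reads.append((rd.name, rd.seq))
        else:
            norm_reads.append((rd[0], rd[1]))

    # Fast path: exact dictionary hit on N-free inserts (counts as unique with
    # 0 mismatches only when no other record is within budget; at budget 0 a
    # dict hit is definitive because inserts are distinct).
    exact: dict[str, str] = {
        r.insert_seq: r.name for r in recs if "N" not in r.insert_seq
    }
    lens = np.array([len(s) for s in seqs])
    width = int(lens.max())
    mat = np.full((len(recs), width), 255, dtype=np.uint8)
    for i, s in enumerate(seqs):
        enc = _encode(s)
        enc = np.where(enc == 0, np.uint8(255), enc)  # library N -> never matches
        mat[i, : len(s)] = enc

    # The dictionary shortcut is only sound when all inserts share one length
    # (otherwise a shorter insert could also match inside its own window) AND
    # an exact hit is provably unique: at budget 0 that follows from inserts
    # being distinct; at budget > 0 it needs the library's minimum pairwise
    # Hamming distance to exceed 2 x max_mismatch (then no second insert can
    # sit within budget of a read at distance 0 from the first).
    uniform = int(lens.min()) == width
    shortcut = uniform and max_mismatch == 0
    if uniform and max_mismatch > 0 and len(recs) > 1:
        min_sep = width + 1
        chunk_rows = max(1, (1 << 24) // (len(recs) * width))
        for lo in range(0, len(recs), chunk_rows):
            block = mat[lo : lo + chunk_rows]
            d = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
            d[np.arange(block.shape[0]), lo + np.arange(block.shape[0])] = width + 1
            min_sep = min(min_sep, int(d.min()))
        shortcut = min_sep > 2 * max_mismatch
    elif uniform and max_mismatch > 0:
        shortcut = True  # single-record library

    out: list[ReadAssignment] = [None] * len(norm_reads)  # type: ignore[list-item]
    scan_idx: list[int] = []
    for i, (name, seq) in enumerate(norm_reads):
        hit = exact.get(seq[:width]) if uniform and len(seq) >= width else None
        if hit is not None and shortcut:
            out[i] = ReadAssignment(name, hit, 0)
        else:
            scan_idx.append(i)

    if scan_idx:
        chunk = 2048
        for lo in range(0, len(scan_idx), chunk):
            idx = scan_idx[lo : lo + chunk]
            enc_reads = np.zeros((len(idx), width), dtype=np.uint8)
            read_lens = np.empty(len(idx), dtype=np.int64)
            for j, i in enumerate(idx):
                seq = norm_reads[i][1][:width]
                enc_reads[j, : len(seq)] = _encode(seq)
                read_lens[j] = len(seq)
            # mismatches over the compared window min(read_len, insert_len)
            cmp_len = np.minimum(read_lens[:, None], lens[None, :])
            pos = np.arange(width)
            diff = enc_reads[:, None, :] != mat[None, :, :]
            in_window = pos[None, None, :] < cmp_len[:, :, None]
            mm = (diff & in_window).sum(axis=2)
            for j, i in enumerate(idx):
                within = np.flatnonzero(mm[j] <= max_mismatch)
                if len(within) == 1:
                    k = int(within[0])
                    out[i] = ReadAssignment(norm_reads[i][0], recs[k].name, int(mm[j, k]))
                else:
                    out[i] = ReadAssignment(norm_reads[i][0], None, None)
    return out


def assignments_to_sam(
    assignments: Sequence[ReadAssignment],
    lib: ReporterLibrary,
    path: str | os.PathLike,
    read_lengths: dict[str, int] | None = None,
    include_unassigned: bool = False,
) -> None:
    """Serialize assignments as SAM (all-match CIGAR, NM tag).

    The aligned length is min(read length, insert length) when read lengths
    are supplied, else the insert length. Unassigned reads are omitted by
    default, mirroring an aligner run with unaligned output suppressed.
    """
    with open_text(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rec in lib:
            fh.write(f"@SQ\tSN:{rec.name}\tLN:{len(rec.insert_seq)}\n")
        for a in assignments:
            if a.reference is None:
                if include_unassigned:
                    fh.write(f"{a.read_name}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
                continue
            ins_len = len(lib[a.reference].insert_seq)
            aln_len = ins_len
            if read_lengths is not None:
                aln_len = min(ins_len, read_lengths[a.read_name])
            fh.write(
                f"{a.read_name}\t0\t{a.reference}\t1\t42\t{aln_len}M\t*\t0\t0\t*\t*\t"
                f"NM:i:{a.mismatches}\n"
            )
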