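"""Declarative read-structure processing: trim, demultiplex, capture UMIs.

The sequencing design puts all sample bookkeeping on read 2, which covers the
RT primer: a 4-nt anchor, a 10-nt UMI, a second 4-nt anchor, a 6-nt in-line
replicate barcode, and the primer's reporter-binding region. Read 1 covers
the variable insert, optionally preceded by 0-2 untemplated "stagger" bases
plus a fixed sequence when the i5 adapter cannot sit directly against the
insert.

Processing a pair therefore means: consume read 2 segments in declared order
(anchors verified within a mismatch budget, barcode matched against a
whitelist, UMI captured into both read names after ``#``), clip read 1 of any
stagger/5' fixed sequence and 3'-trim it at the downstream fixed sequence,
then route the pair to the barcode's output files, to ``undetermined``
(unknown barcode) or to ``discarded`` (failed anchor/register checks).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

from .io import FastqRecord, open_text, read_fastq

DPX_PLACEHOLDER = "[DPX]"

# Default RT-primer segment sequences used by the simulator and the default
# read structure. The anchors validate read register; the binding region is
# the primer's reporter-annealing segment.
DEFAULT_ANCHOR_A = "GTCA"
DEFAULT_ANCHOR_B = "AGCT"
DEFAULT_BINDING = "GATCGGAAGAGCACACGTCT"
DEFAULT_UMI_LENGTH = 10


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Segment:
    """One declared element of a read layout."""

    role: str  # fixed | anchor | barcode | umi | insert
    length: int | None = None
    sequence: str | None = None
    max_mismatch: int = 0

    def __post_init__(self):
        if self.role not in ("fixed", "anchor", "barcode", "umi", "insert"):
            raise ValueError(f"unknown segment role {self.role!r}")
        if self.role in ("fixed", "anchor") and not self.sequence:
            raise ValueError(f"{self.role} segment requires a sequence")
        if self.role in ("barcode", "umi") and not self.length:
            raise ValueError(f"{self.role} segment requires a length")

    @property
    def nbases(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        return self.length or 0


@dataclass
class ReadStructure:
    """Layouts for both mates plus the replicate-barcode whitelist."""

    read1_segments: list[Segment]
    read2_segments: list[Segment]
    barcode_whitelist: dict[str, str]  # barcode sequence -> replicate label
    stagger_offsets: tuple[int, ...] = (0, 1, 2)
    barcode_max_mismatch: int = 0

    def __post_init__(self):
        for segs, which in ((self.read1_segments, "read 1"), (self.read2_segments, "read 2")):
            n_ins = sum(1 for s in segs if s.role == "insert")
            if n_ins > 1:
                raise ValueError(f"{which} declares more than one insert segment")
            if n_ins == 1:
                after = segs[segs.index(next(s for s in segs if s.role == "insert")) + 1 :]
                # the insert consumes the remainder; only a 3'-trim fixed
                # sequence may follow it
                if any(s.role != "fixed" for s in after):
                    raise ValueError(
                        f"{which}: only fixed (3'-trim) segments may follow the insert"
                    )
        lens = {len(b) for b in self.barcode_whitelist}
        if len(lens) > 1:
            raise ValueError("whitelist barcodes have differing lengths")
        for b1, b2 in combinations(self.barcode_whitelist, 2):
            if hamming(b1, b2) <= 2 * self.barcode_max_mismatch:
                raise ValueError(
                    f"barcodes {b1}/{b2} are within 2 x max_mismatch "
                    f"({self.barcode_max_mismatch}); assignment would be ambiguous"
                )

    @classmethod
    def default(
        cls,
        barcodes: dict[str, str] | Iterable[str],
        read1_fixed_5p: str | None = None,
        read1_fixed_3p: str | None = None,
        umi_length: int = DEFAULT_UMI_LENGTH,
        anchor_a: str = DEFAULT_ANCHOR_A,
        anchor_b: str = DEFAULT_ANCHOR_B,
        binding: str = DEFAULT_BINDING,
    ) -> "ReadStructure":
        """The RT-primer default: [anchor 4][UMI][anchor 4][barcode 6][binding]."""
        if not isinstance(barcodes, dict):
            barcodes = {b: b for b in barcodes}
        bc_len = {len(b) for b in barcodes}
        if len(bc_len) != 1:
            raise ValueError("barcodes must share one length")
        r1: list[Segment] = []
        if read1_fixed_5p:
            r1.append(Segment("fixed", sequence=read1_fixed_5p, max_mismatch=1))
        r1.append(Segment("insert"))
        if read1_fixed_3p:
            r1.append(Segment("fixed", sequence=read1_fixed_3p, max_mismatch=1))
        r2 = [
            Segment("anchor", sequence=anchor_a, max_mismatch=1),
            Segment("umi", length=umi_length),
            Segment("anchor", sequence=anchor_b, max_mismatch=1),
            Segment("barcode", length=bc_len.pop()),
            Segment("fixed", sequence=binding, max_mismatch=2),
            Segment("insert"),
        ]
        return cls(r1, r2, dict(barcodes))


@dataclass
class DemuxReport:
    """Per-step read accounting; totals conserve exactly."""

    input_reads: int = 0
    per_barcode: dict[str, int] = field(default_factory=dict)
    undetermined: int = 0
    discarded: int = 0
    discard_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def assigned(self) -> int:
        return sum(self.per_barcode.values())

    def check_conservation(self) -> None:
        total = self.assigned + self.undetermined + self.discarded
        if total != self.input_reads:
            raise AssertionError(
                f"read accounting broken: {total} routed vs {self.input_reads} input"
            )

    def to_dict(self) -> dict:
        return {
            "input_reads": self.input_reads,
            "assigned": self.assigned,
            "per_barcode": dict(sorted(self.per_barcode.items())),
            "undetermined": self.undetermined,
            "discarded": self.discarded,
            "discard_reasons": dict(sorted(self.discard_reasons.items())),
        }

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def detect_stagger(
    read1_seq: str,
    fixed_seq: str,
    offsets: Iterable[int] = (0, 1, 2),
    max_mismatch: int = 1,
) -> int | None:
    """Smallest offset at which the 5' fixed sequence matches within budget.

    Returns ``None`` when no allowed offset matches (caller should discard).
    """
    n = len(fixed_seq)
    for off in sorted(offsets):
        window = read1_seq[off : off + n]
        if len(window) < n:
            continue
        if window == fixed_seq or hamming(window, fixed_seq) <= max_mismatch:
            return off
    return None


def _match_barcode(
    observed: str, whitelist: dict[str, str], max_mismatch: int
) -> str | None:
    """Return the barcode sequence assigned to *observed*, or None."""
    if observed in whitelist:
        return observed
    if max_mismatch == 0:
        return None
    hits = [b for b in whitelist if hamming(observed, b) <= max_mismatch]
    return hits[0] if len(hits) == 1 else None


def _find_fixed_3p(seq: str, fixed: str, max_mismatch: int) -> int | None:
    """Leftmost start of *fixed* in *seq* allowing substitutions, else None."""
    n = len(fixed)
    for start in range(0, len(seq) - n + 1):
        if hamming(seq[start : start + n], fixed) <= max_mismatch:
            return start
    return None


def _base_name(name: str) -> str:
    token = name.split(None, 1)[0]
    if token.endswith("/1") or token.endswith("/2"):
        token = token[:-2]
    return token


def demultiplex(
    fastq_r1: str | os.PathLike,
    fastq_r2: str | os.PathLike,
    structure: ReadStructure,
    out_dir: str | os.PathLike,
    r1_template: str = f"reads_{DPX_PLACEHOLDER}_R1.fastq",
    r2_template: str = f"reads_{DPX_PLACEHOLDER}_R2.fastq",
    report_path: str | os.PathLike | None = None,
) -> DemuxReport:
    """Demultiplex a synchronized FASTQ pair into per-barcode pairs.

    Output filenames substitute the barcode sequence for the ``[DPX]``
    placeholder; reads with an unknown barcode go to an ``undetermined`` pair
    and reads failing anchor/register checks are counted as discarded. The
    UMI is appended to both mates' names after ``#``. A JSON report is
    written when *report_path* is given.
    """
    os.makedirs(out_dir, exist_ok=True)
    report = DemuxReport()
    bins = list(structure.barcode_whitelist) + ["undetermined"]
    handles = {}
    for b in bins:
        p1 = os.path.join(out_dir, r1_template.replace(DPX_PLACEHOLDER, b))
        p2 = os.path.join(out_dir, r2_template.replace(DPX_PLACEHOLDER, b))
        handles[b] = (open_text(p1, "wt"), open_text(p2, "wt"))
        if b != "undetermined":
            report.per_barcode.setdefault(b, 0)

    # Pre-compile the read 2 walk: (role, start, end, payload) with fixed
    # offsets, since every non-insert segment has a declared width.
    plan2 = []
    pos = 0
    for seg in structure.read2_segments:
        if seg.role == "insert":
            plan2.append(("insert", pos, None, None))
            break
        plan2.append((seg.role, pos, pos + seg.nbases, seg))
        pos += seg.nbases

    segs1 = structure.read1_segments
    ins_i = next((i for i, s in enumerate(segs1) if s.role == "insert"), len(segs1))
    r1_fixed_5p = segs1[ins_i - 1] if ins_i >= 1 and segs1[ins_i - 1].role == "fixed" else None
    r1_fixed_3p = (
        segs1[ins_i + 1] if ins_i + 1 < len(segs1) and segs1[ins_i + 1].role == "fixed" else None
    )

    try:
        it2 = read_fastq(fastq_r2)
        for rec1 in read_fastq(fastq_r1):
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError("read 2 file ended before read 1: desynchronized mates")
            if _base_name(rec1.name) != _base_name(rec2.name):
                raise ValueError(
                    f"desynchronized mates: {rec1.name!r} vs {rec2.name!r}"
                )
            report.input_reads += 1

            # --- read 2: anchors / UMI / barcode / binding region ---
            umi = None
            barcode = None
            fail = None
            for role, start, end, seg in plan2:
                if role == "insert":
                    break
                window = rec2.seq[start:end]
                if len(window) < (end - start):
                    fail = "read2_too_short"
                    break
                if role in ("anchor", "fixed"):
                    if window != seg.sequence and hamming(window, seg.sequence) > seg.max_mismatch:
                        fail = f"{role}_mismatch"
                        break
                elif role == "umi":
                    umi = window
                elif role == "barcode":
                    barcode = _match_barcode(
                        window, structure.barcode_whitelist, structure.barcode_max_mismatch
                    )
            if fail is not None:
                report.discarded += 1
                report.discard_reasons[fail] = report.discard_reasons.get(fail, 0) + 1
                continue

            # --- read 1: stagger / 5' fixed clip, then 3' fixed trim ---
            seq1, qual1 = rec1.seq, rec1.qual
            if r1_fixed_5p is not None:
                off = detect_stagger(
                    seq1,
                    r1_fixed_5p.sequence,
                    structure.stagger_offsets,
                    r1_fixed_5p.max_mismatch,
                )
                if off is None:
                    report.discarded += 1
                    report.discard_reasons["no_5p_fixed"] = (
                        report.discard_reasons.get("no_5p_fixed", 0) + 1
                    )
                    continue
                clip = off + len(r1_fixed_5p.sequence)
                seq1, qual1 = seq1[clip:], qual1[clip:]
            if r1_fixed_3p is not None:
                hit = _find_fixed_3p(seq1, r1_fixed_3p.sequence, r1_fixed_3p.max_mismatch)
                if hit is not None:
                    seq1, qual1 = seq1[:hit], qual1[:hit]

            if barcode is None:
                bin_label = "undetermined"
                report.undetermined += 1
            else:
                bin_label = barcode
                report.per_barcode[barcode] = report.per_barcode.get(barcode, 0) + 1

            name1 = f"{_base_name(rec1.name)}#{umi}"
            h1, h2 = handles[bin_label]
            h1.write(f"@{name1}\n{seq1}\n+\n{qual1}\n")
            h2.write(f"@{name1}\n{rec2.seq}\n+\n{rec2.qual}\n")
        try:
            next(it2)
        except StopIteration:
            pass
        else:
            raise ValueError("read 1 file ended before read 2: desynchronized mates")
    finally:
        for h1, h2 in handles.values():
            h1.close()
            h2.close()

    report.check_conservation()
    if report_path is not None:
        report.write_json(report_path)
    return report
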