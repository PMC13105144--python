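"""Synthetic NaP-TRAP experiments with known ground truth.

The generative model is the one the analysis assumes: every reporter has a
true input abundance (log-normal across reporters) and a true translation
efficiency TE (log-normal), and a pulldown library samples molecules with
probability proportional to abundance x TE while an input library samples
proportional to abundance alone. Spike-ins are injected at a configured
fraction of reads, split across the ladder in proportion to the expected
relative amounts (1:5:25:50:125 by default). Each sampled molecule receives
a random UMI, is optionally PCR-duplicated, and is then "sequenced" into a
read pair with per-base substitution errors:

* read 1 — optional stagger bases + optional 5' fixed sequence + the insert
  prefix (the default design starts read 1 at insert base 1);
* read 2 — 4-nt anchor, 10-nt UMI, 4-nt anchor, 6-nt replicate barcode, the
  RT-primer binding region, then reverse-complemented insert.

Replicates of one fraction share a FASTQ pair (they are pooled for
sequencing and separated again by the in-line barcode). Each read name
encodes its generating reporter, barcode, UMI and stagger offset, so any
pipeline stage can be checked against the truth without side tables.
Everything derives from one integer seed; outputs are byte-identical across
runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import open_text
from .library import ReporterLibrary, ReporterRecord, write_library
from .qpcr import CqMeasurement
from .readprep import (
    DEFAULT_ANCHOR_A,
    DEFAULT_ANCHOR_B,
    DEFAULT_BINDING,
    DEFAULT_UMI_LENGTH,
    ReadStructure,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_BARCODES = ("ACTTGA", "GATCAG", "TAGCTT", "CGATGT", "TGACCA", "GCCAAT")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment."""

    seed: int
    n_reporters: int = 500
    n_spikeins: int = 5
    insert_length: int = 124
    read1_length: int = 75
    read2_length: int = 75
    n_replicates: int = 3
    barcodes: tuple[str, ...] = ()  # default: first n_replicates of DEFAULT_BARCODES
    umi_length: int = DEFAULT_UMI_LENGTH
    reads_per_sample: int = 200_000  # unique molecules per (fraction, replicate)
    te_log2_mean: float = 0.0
    te_log2_sd: float = 1.0
    abundance_log2_sd: float = 0.5
    spikein_read_fraction: float = 0.01
    spikein_amounts: tuple[float, ...] = (1, 5, 25, 50, 125)
    error_rate: float = 0.001       # substitutions per base, both mates
    pcr_duplicate_rate: float = 0.0
    stagger_offsets: tuple[int, ...] = (0,)
    read1_fixed_5p: str | None = None  # required if stagger_offsets != (0,)

    def __post_init__(self):
        if not self.barcodes:
            object.__setattr__(
                self, "barcodes", DEFAULT_BARCODES[: self.n_replicates]
            )
        if len(self.barcodes) != self.n_replicates:
            raise ValueError("need one barcode per replicate")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be pairwise distinct")
        for rate in (self.error_rate, self.pcr_duplicate_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        if not (0.001 <= self.spikein_read_fraction <= 0.02):
            raise ValueError(
                "spikein_read_fraction must lie in the recommended 0.1-2% band"
            )
        if self.insert_length < 1 or self.read1_length < 1:
            raise ValueError("lengths must be positive")
        if set(self.stagger_offsets) != {0} and self.read1_fixed_5p is None:
            raise ValueError("stagger offsets require a read1_fixed_5p sequence")
        if self.n_spikeins != len(self.spikein_amounts):
            raise ValueError("one ladder amount per spike-in is required")

    @property
    def sample_labels(self) -> list[str]:
        return [
            f"{fraction}_{rep}"
            for fraction in ("input", "pulldown")
            for rep in range(1, self.n_replicates + 1)
        ]

    def read_structure(self) -> ReadStructure:
        return ReadStructure.default(
            {b: f"rep{i + 1}" for i, b in enumerate(self.barcodes)},
            read1_fixed_5p=self.read1_fixed_5p,
            umi_length=self.umi_length,
        )


@dataclass
class SimResult:
    """Paths plus ground truth for one simulated experiment."""

    config: SimConfig
    library: ReporterLibrary
    library_path: str
    fastq: dict[str, tuple[str, str]]  # fraction -> (R1 path, R2 path)
    truth: pd.DataFrame  # per reporter: true_abundance, true_te
    molecule_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    # molecule_counts[sample_label][record_name] = pre-duplication molecules


def _random_seqs(rng: np.random.Generator, n: int, length: int, distinct_prefix: int) -> list[str]:
    """Random ACGT sequences whose prefixes of *distinct_prefix* nt are unique."""
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        arr = _BASES[rng.integers(0, 4, size=(n - len(seqs), length))]
        for row in arr:
            s = row.tobytes().decode("ascii")
            if s[:distinct_prefix] not in seen:
                seen.add(s[:distinct_prefix])
                seqs.append(s)
    return seqs


def _random_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return arr.view(f"S{length}").ravel()


def _inject_errors(rng: np.random.Generator, seqs: list[str], rate: float) -> list[str]:
    """Per-base substitutions at *rate*; always changes the base."""
    if rate == 0:
        return seqs
    n_err = rng.binomial([len(s) for s in seqs], rate)
    hit = np.flatnonzero(n_err)
    for i in hit:
        s = bytearray(seqs[i], "ascii")
        for pos in rng.choice(len(s), size=n_err[i], replace=False):
            choices = [b for b in b"ACGT" if b != s[pos]]
            s[pos] = choices[rng.integers(0, 3)]
        seqs[i] = s.decode("ascii")
    return seqs


def make_library(cfg: SimConfig, rng: np.random.Generator) -> ReporterLibrary:
    distinct = min(cfg.read1_length, cfg.insert_length)
    seqs = _random_seqs(
        rng, cfg.n_reporters + cfg.n_spikeins, cfg.insert_length, distinct
    )
    records = [
        ReporterRecord(f"rep{i:05d}#reporter", seqs[i], "reporter")
        for i in range(cfg.n_reporters)
    ]
    records += [
        ReporterRecord(f"sp{j + 1}#spikein", seqs[cfg.n_reporters + j], "spikein")
        for j in range(cfg.n_spikeins)
    ]
    return ReporterLibrary(records)


def simulate_experiment(cfg: SimConfig, out_dir: str | os.PathLike) -> SimResult:
    """Write library FASTA + per-fraction FASTQ pairs; return the ground truth."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    lib = make_library(cfg, rng)
    lib_path = os.path.join(out_dir, "library.fa")
    write_library(lib, lib_path)

    names = [r.name for r in lib]
    abundance = 2.0 ** rng.normal(0.0, cfg.abundance_log2_sd, cfg.n_reporters)
    te = 2.0 ** rng.normal(cfg.te_log2_mean, cfg.te_log2_sd, cfg.n_reporters)
    truth = pd.DataFrame(
        {"true_abundance": abundance, "true_te": te},
        index=[r.name for r in lib.reporters],
    )
    spike_p = np.asarray(cfg.spikein_amounts, dtype=float)
    spike_p = spike_p / spike_p.sum()

    qual1 = "I" * (cfg.read1_length)
    fixed5 = cfg.read1_fixed_5p or ""
    fastq: dict[str, tuple[str, str]] = {}
    molecule_counts: dict[str, dict[str, int]] = {}

    for fraction in ("input", "pulldown"):
        weights = abundance * (te if fraction == "pulldown" else 1.0)
        probs = weights / weights.sum()
        r1_path = os.path.join(out_dir, f"sim_{fraction}_R1.fastq")
        r2_path = os.path.join(out_dir, f"sim_{fraction}_R2.fastq")
        fastq[fraction] = (r1_path, r2_path)
        with open_text(r1_path, "wt") as f1, open_text(r2_path, "wt") as f2:
            for rep in range(1, cfg.n_replicates + 1):
                label = f"{fraction}_{rep}"
                barcode = cfg.barcodes[rep - 1]
                n_spike = rng.binomial(cfg.reads_per_sample, cfg.spikein_read_fraction)
                n_rep = cfg.reads_per_sample - n_spike
                rep_counts = rng.multinomial(n_rep, probs)
                sp_counts = rng.multinomial(n_spike, spike_p)
                counts = np.concatenate([rep_counts, sp_counts])
                molecule_counts[label] = {
                    names[i]: int(c) for i, c in enumerate(counts) if c > 0
                }
                _emit_sample(
                    cfg, rng, lib, counts, label, barcode, fixed5, qual1, f1, f2
                )
    return SimResult(cfg, lib, lib_path, fastq, truth, molecule_counts)


def _emit_sample(cfg, rng, lib, counts, label, barcode, fixed5, qual1, f1, f2):
    records = list(lib)
    rec_idx = np.repeat(np.arange(len(records)), counts)
    n_mol = len(rec_idx)
    umis = _random_umis(rng, n_mol, cfg.umi_length)
    # Distinct molecules of one reporter carry distinct UMIs within a sample
    # (two molecules sharing a UMI are indistinguishable from a PCR duplicate,
    # so the truth table could not be exact otherwise). Collisions are rare
    # (10-nt UMI space); regenerate them.
    seen: set[tuple[int, bytes]] = set()
    for m in range(n_mol):
        key = (int(rec_idx[m]), bytes(umis[m]))
        while key in seen:
            umis[m] = _random_umis(rng, 1, cfg.umi_length)[0]
            key = (int(rec_idx[m]), bytes(umis[m]))
        seen.add(key)
    offsets = rng.choice(cfg.stagger_offsets, size=n_mol)
    # reads per molecule: 1 + Geometric-tail duplicates at pcr_duplicate_rate
    if cfg.pcr_duplicate_rate > 0:
        n_reads = rng.geometric(1.0 - cfg.pcr_duplicate_rate, size=n_mol)
    else:
        n_reads = np.ones(n_mol, dtype=np.int64)

    # Per-record constants, hoisted out of the per-molecule loop.
    core_len = (
        len(DEFAULT_ANCHOR_A) + cfg.umi_length + len(DEFAULT_ANCHOR_B)
        + len(barcode) + len(DEFAULT_BINDING)
    )
    tail_len = max(cfg.read2_length - core_len, 0)
    rec_names = [r.name for r in records]
    rec_tails = [r.insert_seq[::-1].translate(_COMP)[:tail_len] for r in records]
    no_stagger = set(cfg.stagger_offsets) == {0}
    rec_r1 = [
        (fixed5 + r.insert_seq[: cfg.read1_length - len(fixed5)])[: cfg.read1_length]
        for r in records
    ]
    r2_mid = DEFAULT_ANCHOR_B + barcode + DEFAULT_BINDING

    r1_list: list[str] = []
    r2_list: list[str] = []
    name_list: list[str] = []
    for m in range(n_mol):
        k = rec_idx[m]
        umi = umis[m].decode("ascii")
        off = int(offsets[m])
        if no_stagger or off == 0:
            r1 = rec_r1[k]
        else:
            stagger = "".join("ACGT"[b] for b in rng.integers(0, 4, size=off))
            prefix = stagger + fixed5
            avail = cfg.read1_length - len(prefix)
            r1 = (prefix + records[k].insert_seq[: max(avail, 0)])[: cfg.read1_length]
        r2 = (DEFAULT_ANCHOR_A + umi + r2_mid + rec_tails[k])[: cfg.read2_length]
        name = f"{label}.{m}:{rec_names[k]}:{barcode}:{umi}:{off}"
        for _ in range(int(n_reads[m])):
            r1_list.append(r1)
            r2_list.append(r2)
            name_list.append(name)

    r1_list = _inject_errors(rng, r1_list, cfg.error_rate)
    r2_list = _inject_errors(rng, r2_list, cfg.error_rate)
    for name, r1, r2 in zip(name_list, r1_list, r2_list):
        f1.write(f"@{name}\n{r1}\n+\n{qual1[: len(r1)]}\n")
        f2.write(f"@{name}\n{r2}\n+\n{'I' * len(r2)}\n")


def _split_name(read_name: str) -> tuple[str, str, str, str, int]:
    """(molecule id, reporter name, barcode, umi, stagger offset).

    Name format: ``<label>.<m>:<reporter name>:<barcode>:<umi>:<off>``; the
    demultiplexer appends ``#<UMI>``, which is ignored here (reporter names
    themselves contain ``#``, hence the right-anchored split).
    """
    head, bc, umi, off = read_name.rsplit(":", 3)
    off = off.split("#", 1)[0]
    ident, reporter = head.split(":", 1)
    return ident, reporter, bc, umi, int(off)


def read_truth(read_name: str) -> tuple[str, str, str, int]:
    """(reporter, barcode, UMI, stagger offset) encoded in a simulated name."""
    _, reporter, bc, umi, off = _split_name(read_name)
    return reporter, bc, umi, off


def simulate_qpcr(
    true_te: Mapping[str, float] | float,
    normalizer: str = "dsRed",
    noise_sd: float = 0.0,
    seed: int = 0,
    n_technical: int = 3,
    base_cq: float = 20.0,
) -> list[CqMeasurement]:
    """Cq table from which the 2^-ddCq pipeline recovers the given TE.

    The normalizer sits at ``base_cq`` in both fractions; each reporter sits
    2 cycles above it in the input and ``2 - log2(TE)`` above in the
    pulldown, plus N(0, noise_sd) per technical replicate. At zero noise,
    recovery is exact.
    """
    if not isinstance(true_te, Mapping):
        true_te = {"reporter": float(true_te)}
    rng = np.random.default_rng(seed)
    out: list[CqMeasurement] = []

    def techs(mu: float) -> tuple[float, ...]:
        return tuple(float(mu + rng.normal(0, noise_sd)) for _ in range(n_technical))

    for fraction in ("input", "pulldown"):
        out.append(CqMeasurement("sim", fraction, normalizer, techs(base_cq)))
    for name, te in true_te.items():
        if te <= 0:
            raise ValueError(f"true TE must be positive, got {te} for {name!r}")
        out.append(CqMeasurement("sim", "input", name, techs(base_cq + 2.0)))
        out.append(
            CqMeasurement("sim", "pulldown", name, techs(base_cq + 2.0 - np.log2(te)))
        )
    return out
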