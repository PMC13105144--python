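"""End-to-end evaluation of the pipeline on simulated experiments.

Runs the full chain — demultiplex, exact read assignment (serialized through
SAM, exactly as aligner output would be consumed), UMI-deduplicated counting,
spike-in normalization, TE — on a :class:`~naptrap.simulate.SimResult` and
scores the estimates against the generator's ground truth.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .counting import CountFilter, CountTable, count_sample, merge_counts
from .io import read_fastq
from .library import assign_reads_exact, assignments_to_sam, parse_library, truncate_inserts
from .quantify import (
    ExperimentDesign,
    SampleInfo,
    Selector,
    SpikeinLadder,
    TeTable,
    apply_selector,
    spikein_factors,
    translation,
)
from .readprep import DemuxReport, demultiplex
from .simulate import SimResult


@dataclass
class EndToEndResult:
    te_table: TeTable
    demux_reports: dict[str, DemuxReport]
    count_tables: list[CountTable]
    metrics: dict[str, float]


def design_for(sim: SimResult, condition: str = "sim") -> ExperimentDesign:
    cfg = sim.config
    samples = [
        SampleInfo(f"{fraction}_{rep}", condition, fraction, rep, cfg.barcodes[rep - 1])
        for fraction in ("input", "pulldown")
        for rep in range(1, cfg.n_replicates + 1)
    ]
    return ExperimentDesign(samples)


def ladder_for(sim: SimResult) -> SpikeinLadder:
    cfg = sim.config
    return SpikeinLadder(
        {f"sp{i + 1}#spikein": float(a) for i, a in enumerate(cfg.spikein_amounts)}
    )


def run_end_to_end(
    sim: SimResult,
    workdir: str | os.PathLike,
    assign_max_mismatch: int = 2,
    min_matches: int | None = None,
    min_input_reads: int = 100,
) -> EndToEndResult:
    """demux -> assign (via SAM) -> count -> normalize -> TE, plus truth metrics.

    The CIGAR-match floor defaults to the aligned length minus the mismatch
    budget (every built-in alignment is all-match); the NM ceiling is the
    assignment mismatch budget.
    """
    cfg = sim.config
    workdir = os.fspath(workdir)
    os.makedirs(workdir, exist_ok=True)
    lib = parse_library(sim.library_path)
    aligned_len = min(cfg.read1_length, cfg.insert_length)
    tlib, _ = truncate_inserts(lib, cfg.read1_length)
    if min_matches is None:
        min_matches = aligned_len - assign_max_mismatch
    cfilter = CountFilter(min_matches, assign_max_mismatch)
    structure = cfg.read_structure()

    demux_reports: dict[str, DemuxReport] = {}
    tables: list[CountTable] = []
    for fraction, (r1, r2) in sim.fastq.items():
        demux_dir = os.path.join(workdir, f"demux_{fraction}")
        demux_reports[fraction] = demultiplex(
            r1, r2, structure, demux_dir,
            r1_template=f"{fraction}_[DPX]_R1.fastq",
            r2_template=f"{fraction}_[DPX]_R2.fastq",
        )
        for rep in range(1, cfg.n_replicates + 1):
            barcode = cfg.barcodes[rep - 1]
            reads = list(read_fastq(os.path.join(demux_dir, f"{fraction}_{barcode}_R1.fastq")))
            assignments = assign_reads_exact(reads, tlib, assign_max_mismatch)
            sam_path = os.path.join(workdir, f"{fraction}_{rep}.sam")
            assignments_to_sam(
                assignments, tlib, sam_path,
                read_lengths={r.name: len(r.seq) for r in reads},
            )
            tables.append(count_sample(sam_path, tlib, cfilter, f"{fraction}_{rep}"))
            os.unlink(sam_path)

    merged = merge_counts(tables, tlib)
    design = design_for(sim)
    ladder = ladder_for(sim)
    factors = spikein_factors(merged, ladder)
    tab = translation(merged, design, factors, tlib)
    selector = Selector("main", ("sim",), min_input_reads)
    apply_selector(tab, design, selector)

    passing = tab.pass_flags["main"]
    passing_names = passing[passing].index
    est = tab.mean_te.loc[passing_names, "sim"].dropna()
    true = sim.truth.loc[est.index, "true_te"]
    if len(est) >= 3:
        r, _ = stats.pearsonr(np.log2(true), np.log2(est))
    else:
        r = math.nan

    spike_names = [rec.name for rec in tlib.spikeins]
    spike_fracs = []
    for label, counts in merged.items():
        total = sum(counts.values())
        if total:
            spike_fracs.append(sum(counts[n] for n in spike_names) / total)
    metrics = {
        "log2_te_pearson_r": float(r),
        "n_passing_reporters": int(len(est)),
        "realized_spikein_fraction": float(np.mean(spike_fracs)),
        "demux_assigned_fraction": float(
            sum(rep.assigned for rep in demux_reports.values())
            / sum(rep.input_reads for rep in demux_reports.values())
        ),
    }
    return EndToEndResult(tab, demux_reports, tables, metrics)
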