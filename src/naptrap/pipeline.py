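"""Stage orchestration: demux -> count -> cutoff -> build -> plots.

Each stage reads the previous stage's artifacts from the configured output
directory and records what it produced in a JSON run manifest (parameters,
input checksums, outputs), so runs are auditable and individually resumable:
re-running a completed stage on unchanged inputs is skipped and noted as
"unchanged" in the manifest.

The built-in exact assigner stands in for an external aligner between demux
and count; drop externally produced SAM/BAM into ``<out>/aligning/`` to use
an aligner instead.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from datetime import datetime, timezone

from . import __version__
from .config import PipelineConfig
from .counting import count_sample, merge_counts, read_count_file, read_cutoff, write_count_file
from .enrichment import define_groups, kmer_enrichment, replicate_correlation
from .library import assign_reads_exact, assignments_to_sam, parse_library, truncate_inserts
from .io import read_fastq
from .quantify import build_tables

log = logging.getLogger("naptrap")

STAGES = ("demux", "count", "cutoff", "build", "plots")


class MissingArtifactError(RuntimeError):
    """An upstream stage has not produced its outputs yet."""

    def __init__(self, stage: str, needed_by: str, detail: str = ""):
        self.stage = stage
        super().__init__(
            f"stage {needed_by!r} needs outputs of stage {stage!r}; run {stage!r} first"
            + (f" ({detail})" if detail else "")
        )


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, path: str):
        self.path = path
        self.data: dict = {"tool": "naptrap", "version": __version__, "stages": {}}
        if os.path.exists(path):
            with open(path) as fh:
                self.data = json.load(fh)

    def note(self, stage: str, params: dict, inputs: list[str], outputs: list[str], status: str):
        self.data["stages"][stage] = {
            "status": status,
            "time": datetime.now(timezone.utc).isoformat(),
            "params": params,
            "inputs": {p: _checksum(p) for p in inputs if os.path.exists(p)},
            "outputs": sorted(outputs),
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def unchanged(self, stage: str, inputs: list[str]) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None or entry.get("status") not in ("done", "unchanged"):
            return False
        prior = entry.get("inputs", {})
        current = {p: _checksum(p) for p in inputs if os.path.exists(p)}
        if prior != current:
            return False
        return all(os.path.exists(p) for p in entry.get("outputs", []))


def _stage_range(stages: str | None) -> list[str]:
    if not stages:
        return list(STAGES)
    if ".." in stages:
        first, last = stages.split("..", 1)
        i = STAGES.index(first or STAGES[0])
        j = STAGES.index(last or STAGES[-1])
        return list(STAGES[i : j + 1])
    return [s for s in stages.split(",") if s]


def run_pipeline(cfg: PipelineConfig, stages: str | None = None) -> dict:
    """Run the requested stage range; returns the manifest mapping."""
    todo = _stage_range(stages)
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = Manifest(os.path.join(cfg.out_dir, "run_manifest.json"))
    demux_dir = os.path.join(cfg.out_dir, "demux")
    align_dir = os.path.join(cfg.out_dir, "aligning")
    count_path = cfg.count_file or os.path.join(cfg.out_dir, "counts.json")
    tables_dir = os.path.join(cfg.out_dir, "tables")
    plots_dir = os.path.join(cfg.out_dir, "plots")

    barcode_map = {
        (s.fraction, s.barcode): s.label for s in cfg.design.samples if s.barcode
    }

    if "demux" in todo:
        from .readprep import ReadStructure, demultiplex

        if not cfg.fastq:
            raise MissingArtifactError("inputs", "demux", "no [[fastq]] entries configured")
        inputs = [fq["r1"] for fq in cfg.fastq] + [fq["r2"] for fq in cfg.fastq]
        if manifest.unchanged("demux", inputs):
            manifest.note("demux", {}, inputs, manifest.data["stages"]["demux"]["outputs"], "unchanged")
            log.info("demux: inputs unchanged, skipping")
        else:
            outputs = []
            barcodes = sorted({s.barcode for s in cfg.design.samples if s.barcode})
            structure = ReadStructure.default(barcodes)
            for fq in cfg.fastq:
                sub = os.path.join(demux_dir, fq["fraction"])
                report = demultiplex(
                    fq["r1"], fq["r2"], structure, sub,
                    r1_template=f"{fq['fraction']}_[DPX]_R1.fastq",
                    r2_template=f"{fq['fraction']}_[DPX]_R2.fastq",
                    report_path=os.path.join(sub, "preparing_report.json"),
                )
                log.info("demux %s: %s", fq["fraction"], report.to_dict())
                outputs += glob.glob(os.path.join(sub, "*.fastq"))
            manifest.note("demux", {"barcodes": barcodes}, inputs, outputs, "done")

    if "count" in todo:
        r1_files = sorted(glob.glob(os.path.join(demux_dir, "*", "*_R1.fastq")))
        r1_files = [p for p in r1_files if "undetermined" not in os.path.basename(p)]
        if not r1_files:
            raise MissingArtifactError("demux", "count", f"no demultiplexed FASTQ under {demux_dir}")
        lib = parse_library(cfg.library)
        if manifest.unchanged("count", r1_files):
            manifest.note("count", {}, r1_files, [count_path], "unchanged")
            log.info("count: inputs unchanged, skipping")
        else:
            os.makedirs(align_dir, exist_ok=True)
            tables = []
            for r1 in r1_files:
                fraction = os.path.basename(os.path.dirname(r1))
                barcode = os.path.basename(r1).split("_")[-2]
                label = barcode_map.get((fraction, barcode))
                if label is None:
                    log.warning("no sample configured for %s/%s; skipping", fraction, barcode)
                    continue
                reads = list(read_fastq(r1))
                read_len = max((len(r.seq) for r in reads), default=0)
                use_lib = lib
                if read_len and read_len < max(len(r.insert_seq) for r in lib):
                    use_lib, _ = truncate_inserts(lib, read_len)
                assignments = assign_reads_exact(reads, use_lib, cfg.assign_max_mismatch)
                sam_path = os.path.join(align_dir, f"{label}.sam")
                lengths = {r.name: len(r.seq) for r in reads}
                assignments_to_sam(assignments, use_lib, sam_path, read_lengths=lengths)
                tables.append(count_sample(sam_path, use_lib, cfg.count_filter, label))
            merged = merge_counts(tables, lib)
            write_count_file(merged, count_path)
            manifest.note(
                "count",
                {"m1": cfg.count_filter.min_matches, "d1": cfg.count_filter.max_edit_distance},
                r1_files, [count_path], "done",
            )

    if "cutoff" in todo:
        if not os.path.exists(count_path):
            raise MissingArtifactError("count", "cutoff", f"{count_path} not found")
        lib = parse_library(cfg.library)
        cutoff_dir = os.path.join(cfg.out_dir, "cutoff")
        read_cutoff(count_path, lib=lib, out_dir=cutoff_dir, fig_format=cfg.fig_format)
        manifest.note("cutoff", {}, [count_path], sorted(glob.glob(os.path.join(cutoff_dir, "*"))), "done")

    te_table = None
    if "build" in todo:
        if not os.path.exists(count_path):
            raise MissingArtifactError("count", "build", f"{count_path} not found")
        lib = parse_library(cfg.library)
        counts = read_count_file(count_path)
        te_table = build_tables(
            counts, cfg.design, lib, cfg.selectors, tables_dir,
            db_path=cfg.db_path,
            ladder=cfg.ladder if cfg.normalization == "spikein" else None,
            te_function=cfg.te_function,
        )
        manifest.note(
            "build", {"normalization": cfg.normalization, "te_function": cfg.te_function},
            [count_path], sorted(glob.glob(os.path.join(tables_dir, "*.csv"))), "done",
        )

    if "plots" in todo:
        if te_table is None:
            if not os.path.exists(count_path):
                raise MissingArtifactError("build", "plots", "no tables built")
            lib = parse_library(cfg.library)
            counts = read_count_file(count_path)
            te_table = build_tables(
                counts, cfg.design, lib, cfg.selectors, tables_dir,
                db_path=cfg.db_path,
                ladder=cfg.ladder if cfg.normalization == "spikein" else None,
                te_function=cfg.te_function,
            )
        lib = parse_library(cfg.library)
        seqs = {r.name: r.insert_seq for r in lib.reporters}
        outputs = []
        for sel in cfg.selectors:
            filt = te_table.filtered(sel.name)
            replicate_correlation(
                filt.te, out_dir=plots_dir, fig_format=cfg.fig_format, prefix=f"{sel.name}_replicates"
            )
            for cond in filt.mean_te.columns:
                groups = define_groups(filt.mean_te[cond], cfg=cfg.enrichment)
                background = {
                    n: seqs[n] for n in filt.mean_te[cond].dropna().index if n in seqs
                }
                kmer_enrichment(
                    groups, background, cfg.enrichment,
                    out_dir=os.path.join(plots_dir, f"{sel.name}_{cond}"),
                    fig_format=cfg.fig_format,
                )
            outputs += glob.glob(os.path.join(plots_dir, "**", "*"), recursive=True)
        manifest.note("plots", {}, [count_path], sorted(set(outputs)), "done")

    return manifest.data
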