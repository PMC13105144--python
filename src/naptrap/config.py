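"""TOML experiment/selector configuration parsing and validation.

Validation is collect-all rather than fail-fast: a bad document produces one
:class:`ConfigError` listing every violation. Unknown keys warn (forward
compatibility); missing required keys are errors. Store paths must be
absolute (the relational store is opened from arbitrary working
directories).
"""

from __future__ import annotations

import os
import tomllib
import warnings
from dataclasses import dataclass, field

from .counting import CountFilter
from .enrichment import EnrichmentConfig
from .quantify import ExperimentDesign, SampleInfo, Selector, SpikeinLadder

_KNOWN_TOP = {"experiment", "samples", "fastq", "enrichment", "counting", "paths", "selectors"}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class PipelineConfig:
    name: str
    library: str
    design: ExperimentDesign
    selectors: list[Selector]
    out_dir: str
    db_path: str | None = None
    count_file: str | None = None
    fastq: list[dict] = field(default_factory=list)  # [{fraction, r1, r2}]
    ladder: SpikeinLadder | None = None
    normalization: str = "spikein"  # or "total"
    te_function: str = "ratio"
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    count_filter: CountFilter = field(default_factory=lambda: CountFilter(100, 4))
    assign_max_mismatch: int = 2
    fig_format: str = "pdf"

    def to_dict(self) -> dict:
        """Round-trippable plain mapping (validate -> serialize -> validate
        is a fixed point)."""
        doc: dict = {
            "experiment": {
                "name": self.name,
                "library": self.library,
                "normalization": self.normalization,
                "translation_function": self.te_function,
                "fig_format": self.fig_format,
            },
            "samples": [
                {
                    "label": s.label,
                    "condition": s.condition,
                    "fraction": s.fraction,
                    "replicate": s.replicate,
                    **({"barcode": s.barcode} if s.barcode else {}),
                }
                for s in self.design.samples
            ],
            "fastq": list(self.fastq),
            "enrichment": {
                "rnum": self.enrichment.rnum,
                "klen": self.enrichment.klen,
                "pseudocount": self.enrichment.pseudocount,
            },
            "counting": {
                "m1": self.count_filter.min_matches,
                "d1": self.count_filter.max_edit_distance,
                "assign_max_mismatch": self.assign_max_mismatch,
            },
            "paths": {
                "out_dir": self.out_dir,
                **({"db": self.db_path} if self.db_path else {}),
                **({"count_file": self.count_file} if self.count_file else {}),
            },
            "selectors": [
                {
                    "name": sel.name,
                    "conditions": list(sel.conditions),
                    "min_input_reads": sel.min_input_reads,
                }
                for sel in self.selectors
            ],
        }
        if self.ladder is not None:
            doc["experiment"]["spikein_ladder"] = dict(self.ladder.amounts)
        return doc


def load_toml(path: str | os.PathLike) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def validate_config(document: dict | str | os.PathLike) -> PipelineConfig:
    """Resolve and validate a configuration document (mapping or TOML path)."""
    if not isinstance(document, dict):
        document = load_toml(document)
    errors: list[str] = []
    for key in document:
        if key not in _KNOWN_TOP:
            warnings.warn(f"unknown configuration section {key!r} ignored", stacklevel=2)

    exp = document.get("experiment", {})
    name = exp.get("name")
    if not name:
        errors.append("experiment.name is required")
    library = exp.get("library")
    if not library:
        errors.append("experiment.library (reporter FASTA path) is required")

    samples: list[SampleInfo] = []
    labels: set[str] = set()
    for i, s in enumerate(document.get("samples", [])):
        missing = [k for k in ("label", "condition", "fraction", "replicate") if k not in s]
        if missing:
            errors.append(f"samples[{i}] missing keys {missing}")
            continue
        if s["fraction"] not in ("input", "pulldown"):
            errors.append(f"samples[{i}].fraction must be input/pulldown, got {s['fraction']!r}")
            continue
        if s["label"] in labels:
            errors.append(f"duplicate sample label {s['label']!r}")
            continue
        labels.add(s["label"])
        samples.append(
            SampleInfo(s["label"], s["condition"], s["fraction"], int(s["replicate"]), s.get("barcode"))
        )
    if not samples:
        errors.append("at least one [[samples]] entry is required")
    design = ExperimentDesign(samples) if samples else None
    if design is not None:
        for cond in design.conditions:
            try:
                design.pairs(cond)
            except ValueError as exc:
                errors.append(str(exc))

    conditions = set(design.conditions) if design else set()
    selectors: list[Selector] = []
    for i, sel in enumerate(document.get("selectors", [])):
        if "name" not in sel or "conditions" not in sel:
            errors.append(f"selectors[{i}] requires 'name' and 'conditions'")
            continue
        if not sel["conditions"]:
            errors.append(f"selector {sel['name']!r} selects no conditions")
            continue
        unknown = [c for c in sel["conditions"] if c not in conditions]
        if unknown:
            errors.append(f"selector {sel['name']!r} references undefined conditions {unknown}")
            continue
        selectors.append(
            Selector(sel["name"], tuple(sel["conditions"]), int(sel.get("min_input_reads", 100)))
        )

    paths = document.get("paths", {})
    out_dir = paths.get("out_dir")
    if not out_dir:
        errors.append("paths.out_dir is required")
    db_path = paths.get("db")
    if db_path is not None and not os.path.isabs(db_path):
        errors.append(
            f"paths.db must be an absolute path (got {db_path!r}); the store is "
            "opened from arbitrary working directories"
        )

    ladder = None
    if "spikein_ladder" in exp:
        try:
            ladder = SpikeinLadder(dict(exp["spikein_ladder"]))
        except ValueError as exc:
            errors.append(f"experiment.spikein_ladder: {exc}")
    normalization = exp.get("normalization", "spikein" if ladder else "total")
    if normalization not in ("spikein", "total"):
        errors.append(f"experiment.normalization must be spikein/total, got {normalization!r}")
    if normalization == "spikein" and ladder is None:
        errors.append("spike-in normalization requires experiment.spikein_ladder")
    te_function = exp.get("translation_function", "ratio")
    if te_function not in ("ratio", "log2_ratio"):
        errors.append(f"experiment.translation_function must be ratio/log2_ratio, got {te_function!r}")

    enr_doc = document.get("enrichment", {})
    try:
        enrichment = EnrichmentConfig(
            rnum=float(enr_doc.get("rnum", 0.1)),
            klen=int(enr_doc.get("klen", 5)),
            pseudocount=float(enr_doc.get("pseudocount", 0.5)),
        )
    except ValueError as exc:
        errors.append(f"enrichment: {exc}")
        enrichment = EnrichmentConfig()

    cnt = document.get("counting", {})
    try:
        count_filter = CountFilter(int(cnt.get("m1", 100)), cnt.get("d1", 4))
    except ValueError as exc:
        errors.append(f"counting: {exc}")
        count_filter = CountFilter()

    fastq = []
    for i, fq in enumerate(document.get("fastq", [])):
        missing = [k for k in ("fraction", "r1", "r2") if k not in fq]
        if missing:
            errors.append(f"fastq[{i}] missing keys {missing}")
            continue
        fastq.append(dict(fq))

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        name=name,
        library=library,
        design=design,
        selectors=selectors,
        out_dir=out_dir,
        db_path=db_path,
        count_file=paths.get("count_file"),
        fastq=fastq,
        ladder=ladder,
        normalization=normalization,
        te_function=te_function,
        enrichment=enrichment,
        count_filter=count_filter,
        assign_max_mismatch=int(cnt.get("assign_max_mismatch", 2)),
        fig_format=exp.get("fig_format", "pdf"),
    )
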