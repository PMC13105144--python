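"""qPCR translation and stability calculator (2^-ddCq).

Technical-replicate Cq values are averaged per (sample, fraction, target);
each fraction's reporter Cq is normalized against a co-delivered spike-in
(e.g. dsRed) to give dCq, and translation is 2^-(dCq_pulldown - dCq_input).

Sign convention (stated explicitly because Cq arithmetic is error-prone):
ddCq = dCq_pulldown - dCq_input, so a reporter that amplifies EARLIER in the
pulldown than the input balance (more ribosome-associated copies) has
negative ddCq and a translation value above 1. Stability between two input
timepoints is analogous with ddCq = dCq_t1 - dCq_t2: a fold change above 1
means the reporter is more abundant (relative to the normalizer) at t1.

Amplification efficiency is fixed at 2 per cycle; per-primer efficiency
correction is out of scope.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from statistics import mean
from typing import Iterable, Mapping

import pandas as pd

MAX_TECH_SPREAD = 0.5  # cycles; wider technical replicates trigger a warning


@dataclass(frozen=True)
class CqMeasurement:
    """Technical-replicate Cq values for one (sample, fraction, target)."""

    sample: str
    fraction: str  # "input" | "pulldown"
    target: str
    cq_values: tuple[float, ...]

    def __post_init__(self):
        if not self.cq_values:
            raise ValueError("at least one technical replicate Cq is required")
        if any(not (v > 0) for v in self.cq_values):
            raise ValueError(f"Cq values must be finite and positive: {self.cq_values}")

    @property
    def mean_cq(self) -> float:
        spread = max(self.cq_values) - min(self.cq_values)
        if spread > MAX_TECH_SPREAD:
            warnings.warn(
                f"{self.sample}/{self.fraction}/{self.target}: technical-replicate "
                f"Cq spread {spread:.2f} exceeds {MAX_TECH_SPREAD} cycles",
                stacklevel=2,
            )
        return mean(self.cq_values)


@dataclass(frozen=True)
class QpcrResult:
    reporter: str
    dcq_input: float
    dcq_pulldown: float
    ddcq: float
    translation_value: float


def _mean_cq(
    measurements: Iterable[CqMeasurement], fraction: str, target: str
) -> float:
    hits = [m for m in measurements if m.fraction == fraction and m.target == target]
    if not hits:
        raise ValueError(f"no Cq measurement for target {target!r} in fraction {fraction!r}")
    return mean(m.mean_cq for m in hits)


def ddcq_translation(
    measurements: Iterable[CqMeasurement], reporter: str, normalizer: str
) -> QpcrResult:
    """Translation value 2^-(dCq_pulldown - dCq_input), spike-in normalized."""
    measurements = list(measurements)
    dcq = {}
    for fraction in ("input", "pulldown"):
        dcq[fraction] = _mean_cq(measurements, fraction, reporter) - _mean_cq(
            measurements, fraction, normalizer
        )
    ddcq = dcq["pulldown"] - dcq["input"]
    return QpcrResult(reporter, dcq["input"], dcq["pulldown"], ddcq, 2.0 ** (-ddcq))


def ddcq_stability(
    measurements_t1: Iterable[CqMeasurement],
    measurements_t2: Iterable[CqMeasurement],
    reporter: str,
    normalizer: str,
) -> QpcrResult:
    """Input-fraction abundance fold change of t1 relative to t2."""
    d1 = _mean_cq(list(measurements_t1), "input", reporter) - _mean_cq(
        list(measurements_t1), "input", normalizer
    )
    d2 = _mean_cq(list(measurements_t2), "input", reporter) - _mean_cq(
        list(measurements_t2), "input", normalizer
    )
    ddcq = d1 - d2
    return QpcrResult(reporter, d1, d2, ddcq, 2.0 ** (-ddcq))


def read_cq_table(path: str | os.PathLike) -> list[CqMeasurement]:
    """Long-format CSV: sample, fraction, target, well, cq (one row per well)."""
    df = pd.read_csv(path)
    required = {"sample", "fraction", "target", "cq"}
    missing = required - set(c.lower() for c in df.columns)
    if missing:
        raise ValueError(f"Cq table lacks columns {sorted(missing)}")
    df.columns = [c.lower() for c in df.columns]
    out = []
    for (sample, fraction, target), grp in df.groupby(
        ["sample", "fraction", "target"], sort=True
    ):
        out.append(
            CqMeasurement(str(sample), str(fraction), str(target), tuple(grp["cq"]))
        )
    return out


def write_results(results: Iterable[QpcrResult], path: str | os.PathLike) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, index=False)
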