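"""Reporter-design calculators.

Three small pieces of bench arithmetic that precede any sequencing:

* UTR tiling — sample each sequence with a fixed-length sliding window
  (default 124 nt, step 25 nt) and wrap each window in the two fixed flanks
  (default 24 + 22 nt) to produce synthesis-ready oligos (170 nt with the
  defaults).
* spike-in dilution / mastermix math — serial dilutions ("1:R" = 1 part in R
  total) down to fg/uL working stocks and C1V1 = C2V2 volumes for the pooled
  mastermix.
* PCR cycle optimization — from a qPCR amplification curve, the recommended
  library-amplification cycle count is (first cycle reaching half of the
  maximum RFU) minus 4, floored at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence


@dataclass(frozen=True)
class TilingSpec:
    window: int = 124
    step: int = 25
    flank5: str = "GGACATTTATTTGGAGCTGCACGG"    # 24 nt
    flank3: str = "GCCACCATGGACTACAAGGACG"      # 22 nt
    anchor_final_window: bool = False

    def __post_init__(self):
        if not (1 <= self.step <= self.window):
            raise ValueError("require 1 <= step <= window")
        if self.flank5 == self.flank3:
            raise ValueError("the two fixed flanks must be distinct (assembly polarity)")


@dataclass(frozen=True)
class OligoRecord:
    name: str
    source: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    oligo_seq: str
    whole_sequence: bool = False  # source shorter than the window


def tile_sequences(
    sequences: Mapping[str, str], spec: TilingSpec = TilingSpec()
) -> list[OligoRecord]:
    """Tile each sequence into flanked oligos.

    Windows start at 0, step, 2*step, ... while start + window <= length.
    With ``anchor_final_window`` an extra window ending exactly at the 3' end
    is added when the last regular window falls short. Sequences shorter than
    the window are emitted whole (flagged, since their oligos are short).
    """
    out: list[OligoRecord] = []
    for name, seq in sequences.items():
        for i, c in enumerate(seq):
            if c not in "ACGT":
                raise ValueError(f"{name}: non-ACGT character {c!r} at position {i + 1}")
        n = len(seq)
        if n < spec.window:
            out.append(
                OligoRecord(
                    f"{name}|1-{n}", name, 1, n,
                    spec.flank5 + seq + spec.flank3, whole_sequence=True,
                )
            )
            continue
        starts = list(range(0, n - spec.window + 1, spec.step))
        if spec.anchor_final_window and starts[-1] + spec.window < n:
            starts.append(n - spec.window)
        for s in starts:
            window = seq[s : s + spec.window]
            out.append(
                OligoRecord(
                    f"{name}|{s + 1}-{s + spec.window}", name, s + 1, s + spec.window,
                    spec.flank5 + window + spec.flank3,
                )
            )
    return out


@dataclass(frozen=True)
class DilutionStep:
    """One 'part in total' dilution, e.g. 2 uL into 1998 uL diluent = 1:1000."""

    part: float
    diluent: float

    def __post_init__(self):
        if self.part <= 0 or self.diluent < 0:
            raise ValueError("part must be > 0 and diluent >= 0")

    @classmethod
    def ratio(cls, r: float) -> "DilutionStep":
        """'1:R' shorthand — 1 part in R total."""
        if r <= 0:
            raise ValueError("dilution ratio must be positive")
        return cls(1.0, r - 1.0)

    @property
    def factor(self) -> float:
        return self.part / (self.part + self.diluent)


def serial_dilution(stock_concentration: float, steps: Sequence[DilutionStep]) -> float:
    """Final concentration after the dilution chain (same unit as the stock).

    Order-invariant (a product of factors); unit changes (ng -> pg -> fg) are
    the caller's bookkeeping: 1000 ng/uL through 1:1000, 1:1000, 1:10 is
    1e-6 ng/uL = 100 fg/uL.
    """
    if stock_concentration <= 0:
        raise ValueError("stock concentration must be positive")
    conc = stock_concentration
    for step in steps:
        conc *= step.factor
    return conc


@dataclass
class MixPlan:
    """C1V1 = C2V2 volumes for pooling spike-ins into one mastermix."""

    volumes: dict[str, float]  # spike-in -> uL to add
    water: float               # uL of diluent to reach final_volume
    final_volume: float        # uL

    @property
    def total_spikein_volume(self) -> float:
        return sum(self.volumes.values())


def mix_plan(
    working: Mapping[str, float],
    desired: Mapping[str, float],
    final_volume: float,
) -> MixPlan:
    """Volumes of each working stock for the desired final concentrations.

    volume_i = desired_i * final_volume / working_i; the remainder is water.
    Errors if the components alone exceed the final volume.
    """
    if final_volume <= 0:
        raise ValueError("final_volume must be positive")
    if set(desired) - set(working):
        raise KeyError(f"no working concentration for {sorted(set(desired) - set(working))}")
    volumes = {}
    for name, c2 in desired.items():
        c1 = working[name]
        if c1 <= 0 or c2 < 0:
            raise ValueError(f"{name}: concentrations must be positive (desired may be 0)")
        volumes[name] = c2 * final_volume / c1
    water = final_volume - sum(volumes.values())
    if water < 0:
        raise ValueError(
            f"infeasible mix: component volumes sum to {sum(volumes.values()):g} uL "
            f"> final volume {final_volume:g} uL"
        )
    return MixPlan(volumes, water, final_volume)


def pcr_cycles(rfu_by_cycle: Sequence[float], subtract: int = 4) -> int:
    """Recommended amplification cycles from a qPCR curve.

    First cycle (1-based) whose RFU reaches half the curve maximum, minus
    ``subtract`` (default 4), floored at 1. A flat zero curve is an error.
    """
    if len(rfu_by_cycle) == 0:
        raise ValueError("empty fluorescence curve")
    peak = max(rfu_by_cycle)
    if peak <= 0:
        raise ValueError("flat zero fluorescence curve: no amplification detected")
    half = peak / 2.0
    for cycle, rfu in enumerate(rfu_by_cycle, start=1):
        if rfu >= half:
            return max(1, cycle - subtract)
    raise AssertionError("unreachable: the max itself reaches half-max")
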