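"""Reporter-design arithmetic: UTR tiling, spike-in mastermix, PCR cycles.

The calculators that precede any sequencing: tile a 5'-UTR into fixed-length
oligos with assembly flanks, plan the spike-in mastermix with C1V1 = C2V2,
and pick a library-amplification cycle count from a qPCR curve.
"""

import numpy as np

from naptrap.design import (
    DilutionStep,
    TilingSpec,
    mix_plan,
    pcr_cycles,
    serial_dilution,
    tile_sequences,
)

# --- tile a 174-nt 5'-UTR with the default 124-nt window / 25-nt step ---
rng = np.random.default_rng(4)
utr = "".join("ACGT"[b] for b in rng.integers(0, 4, 174))
oligos = tile_sequences({"my_utr": utr}, TilingSpec())
print(f"{len(oligos)} windows from a {len(utr)}-nt UTR:")
for o in oligos:
    print(f"  {o.name}  oligo length {len(o.oligo_seq)} nt")

# --- working stock: 1000 ng/uL IVT yield through 1:1000, 1:1000, 1:10 ---
steps = [DilutionStep.ratio(1000), DilutionStep.ratio(1000), DilutionStep.ratio(10)]
fg = serial_dilution(1000.0, steps) * 1e6  # ng/uL -> fg/uL
print(f"\nworking stock after the dilution chain: {fg:g} fg/uL")

# --- mastermix to 1/5/25/50/125 fg/uL in 500 uL ---
working = {"sp1": 100.0, "sp2": 100.0, "sp3": 1000.0, "sp4": 1000.0, "sp5": 1000.0}
desired = {"sp1": 1.0, "sp2": 5.0, "sp3": 25.0, "sp4": 50.0, "sp5": 125.0}
plan = mix_plan(working, desired, 500.0)
for name, v in plan.volumes.items():
    print(f"  {name}: add {v:g} uL")
print(f"  total spike-in {plan.total_spikein_volume:g} uL + water {plan.water:g} uL")

# --- amplification cycles: half of max RFU minus 4 ---
cycles = np.arange(1, 36)
rfu = 1200 / (1 + np.exp(-1.1 * (cycles - 20)))
print(f"\nrecommended amplification cycles: {pcr_cycles(list(rfu))}")
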