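"""Translation values from qPCR Cq tables with the 2^-ddCq scheme.

A reporter measured in input and pulldown fractions is normalized against a
co-delivered dsRed spike-in in each fraction (dCq), and the pulldown dCq is
normalized by the input dCq (ddCq). Translation = 2^-ddCq: above 1 means the
reporter amplifies earlier in the pulldown balance, i.e. is well translated.
"""

from naptrap.qpcr import CqMeasurement, ddcq_translation
from naptrap.simulate import simulate_qpcr

# hand-entered plate: reporter one cycle later than dsRed in the input,
# but level with it in the pulldown -> ddCq = -1 -> translation 2
plate = [
    CqMeasurement("s1", "input", "reporterA", (21.1, 20.9, 21.0)),
    CqMeasurement("s1", "input", "dsRed", (20.0, 20.0, 20.0)),
    CqMeasurement("s1", "pulldown", "reporterA", (20.0, 20.1, 19.9)),
    CqMeasurement("s1", "pulldown", "dsRed", (20.0, 20.0, 20.0)),
]
res = ddcq_translation(plate, "reporterA", "dsRed")
print(f"hand plate:  ddCq={res.ddcq:+.3f}  translation={res.translation_value:.3f}")

# simulated plate built so the pipeline recovers a known TE exactly
for true_te in (0.25, 1.0, 4.0):
    m = simulate_qpcr(true_te, noise_sd=0.0)
    r = ddcq_translation(m, "reporter", "dsRed")
    print(f"simulated TE={true_te:<5}  recovered translation={r.translation_value:.3f}")
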