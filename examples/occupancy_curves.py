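"""Trisite vs bisite catalytic-site filling across the ATP range.

Computes the fraction of enzyme with all three catalytic sites occupied
(the catalytically competent species in trisite catalysis) and the
pooled two-site fractions, for both published sets of site dissociation
constants, and compares the trisite curve with the normalized
Michaelis-Menten activity it is supposed to track.
"""

import numpy as np

from oxex import (
    EF1_KD,
    MF1_KD,
    bisite_activity_fraction,
    normalized_activity,
    trisite_activity_fraction,
)

VMAX, KM = 640.0, 99.0
grid = np.array([0.11, 1.0, 5.0, 30.0, 99.0, 500.0, 5000.0])

tri_mf1 = trisite_activity_fraction(grid, MF1_KD)
tri_ef1 = trisite_activity_fraction(grid, EF1_KD)
bi_mf1 = bisite_activity_fraction(grid, MF1_KD, ("110", "101", "011"))
activity = normalized_activity(VMAX * grid / (KM + grid), VMAX)

print(f"MF1 Kd set: ({MF1_KD.kd1}, {MF1_KD.kd2}, {MF1_KD.kd3}) uM;  "
      f"EF1-style set: ({EF1_KD.kd1}, {EF1_KD.kd2}, {EF1_KD.kd3}) uM")
print()
print("ATP (uM)   f(111) MF1   f(111) EF1   bisite MF1   v/Vmax")
for s, a, b, c, d in zip(grid, tri_mf1, tri_ef1, bi_mf1, activity):
    print(f"{s:8.2f} {a:12.4f} {b:12.4f} {c:12.4f} {d:8.4f}")

print()
print("The trisite fraction rises monotonically with ATP and tracks the")
print("normalized hydrolysis activity; the pooled bisite fraction rises and")
print("then falls as the third site fills, so bisite species cannot carry")
print("the measured activity at saturating ATP.")
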