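"""Forward exchange kinetics: extent of oxygen exchange vs ATP concentration.

Builds the uptake-law prediction X = 1 - 0.75 exp(-k/v) at a few medium
ATP concentrations (velocities from the Michaelis-Menten law) and inverts
a measured mean 18O/P back to the dimensionless exchange progress kt.
"""

import numpy as np

from oxex import extent_from_kt, kt_from_extent, o18_per_p_to_extent

K, VMAX, KM = 10.5, 640.0, 99.0

print("ATP (uM)   v (1/s)   time 1/v (s)   extent X   18O/P")
for s in (0.11, 1.0, 10.0, 100.0, 1000.0, 5000.0):
    v = VMAX * s / (KM + s)
    ext = extent_from_kt(K / v, 0.25)
    print(f"{s:8.2f} {v:9.2f} {1 / v:13.4f} {ext.X:10.4f} {ext.o18_per_p:7.3f}")

print()
print("Low ATP -> long catalytic cycles -> near-complete exchange (X -> 1);")
print("high ATP -> short cycles -> only the hydrolytic water oxygen (X -> 0.25).")

o18 = 2.10  # a measured mean label count per Pi
x = o18_per_p_to_extent(o18)
print(f"\nMeasured 18O/P = {o18} -> X = {x:.4f} -> kt = {kt_from_extent(x):.4f}")
print("kt is the product of the apparent rate constant and the exchange time.")
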