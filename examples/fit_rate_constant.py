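"""Estimate the apparent exchange rate constant from noisy uptake data.

Simulates 18O/P measurements (10^4 Pi molecules per condition) at 15
velocities spanning the experimental range 3.5-650 1/s, then fits the
zero-intercept regression of ln[0.75/(1-X)] on the exchange time 1/v.
"""

import numpy as np

from oxex import ExchangeObservation, fit_rate_constant, simulate_uptake_extent

K_TRUE = 10.5
rng = np.random.default_rng(2026)

observations = []
for v in np.geomspace(3.5, 650.0, 15):
    extent = simulate_uptake_extent(K_TRUE / v, 10_000, rng)
    observations.append(
        ExchangeObservation(
            velocity=float(v), o18_per_p=extent.o18_per_p, convention="uptake"
        )
    )

fit = fit_rate_constant(observations)
k, se = fit.estimates["k"], fit.standard_errors["k"]
print(f"generating k = {K_TRUE} 1/s")
print(f"estimated  k = {k:.3f} +/- {se:.3f} 1/s   (R^2 = {fit.r_squared:.5f})")
print()
print("A single rate constant describes the exchange across two decades of")
print("velocity: the extent of exchange is set by the time available (1/v),")
print("not by any velocity-dependent change in the exchange rate itself.")
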