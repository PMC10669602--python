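# oxex — oxygen-exchange kinetics of ATP hydrolysis by F₁-ATPase

During ATP hydrolysis by F₁-ATPase, oxygen atoms of enzyme-bound
phosphate (or of the γ-phosphoryl of bound ATP) exchange with water
oxygens before the product Pi is released — the *intermediate Pi–HOH
exchange*. The exchange is read out by ¹⁸O labeling: either as the mean
number of labeled oxygens per released Pi (¹⁸O/P, 0–4) or as the full
GC-MS isotopomer distribution of Pi species carrying 3, 2, 1 or 0
labels. `oxex` is a small scientific Python library for analyzing such
data: it implements the closed-form exchange kinetics, estimates the
apparent exchange rate constant, determines how many catalytic sites
exchange simultaneously, and models catalytic-site occupancy to
discriminate trisite from bisite catalysis. A seeded stochastic
simulator of the whole measurement chain makes every inference stage
testable without laboratory data.

## The model

**Extent of exchange (uptake configuration).** With the label in water,
the fraction X of labeled Pi oxygens obeys dX/dt = k(1 − X) with
X(0) = X_i, so

    X(t) = 1 − (1 − X_i) e^(−kt),    ln[(1 − X_i)/(1 − X)] = kt.

One of the four Pi oxygens always comes from the water molecule consumed
by bond cleavage, fixing X_i = 1/4; hence kt = ln[0.75/(1 − X)] with
X = ¹⁸O/P ⁄ 4. The same X(t) results whether exchange precedes or
follows hydrolysis (pathway independence). The exchange time available
at a catalytic site is the reciprocal of the steady-state hydrolysis
velocity v, multiplied by the number n of sites exchanging at once:
t = n/v.

**Isotopomer distributions (washout configuration).** With the label on
the γ-phosphoryl of ATP, each Pi loses labels one at a time through a
constant-rate event chain A₁ → A₂ → A₃ → A₄ (3 → 0 labels) — a Poisson
process per molecule. Writing A_i in percent,

    A₁ = A₁₀ e^(−kt)
    A₂ = A₁₀ kt e^(−kt) + A₂₀ e^(−kt)
    A₃ = A₁₀ (kt)² e^(−kt)/2 + A₂₀ kt e^(−kt) + A₃₀ e^(−kt)
    A₄ = 100 − A₁ − A₂ − A₃.

**Inference.** k is the slope of the zero-intercept regression of
ln[0.75/(1 − X)] on t; the site count n ∈ {1, 2, 3} is selected per
condition by least-squares comparison of the predicted and measured
distributions; the n = 3 → n = 2 transition is located along the
exchange-time axis. Site occupancy fractions follow from the grand
partition function over the eight occupancy patterns of three
independent sites with dissociation constants K_d1 ≤ K_d2 ≤ K_d3, e.g.
f(111) = ∏ᵢ S/(S + K_dᵢ).

## Worked example

Fitting the apparent exchange rate constant from simulated noisy ¹⁸O/P
measurements (10⁴ Pi molecules per condition, 15 velocities spanning
3.5–650 s⁻¹):

```sh
$ python examples/fit_rate_constant.py
generating k = 10.5 1/s
estimated  k = 10.482 +/- 0.030 1/s   (R^2 = 0.99988)
```

The estimate recovers the generating constant to well under 1 %, and the
linearized law stays straight (R² ≈ 1) across two decades of velocity:
the extent of exchange is controlled by the time available for exchange
(1/v), not by any velocity-dependent change of the rate constant itself.
The other scripts in `examples/` each demonstrate one capability —
forward kinetics, isotopomer washout, site-count selection and the
regime transition, occupancy curves, and the full pipeline — and print a
short interpretation with their numbers.

A thin command-line interface mirrors the pipeline
(`oxex simulate | fit-k | predict-dist | select-n | detect-transition |
occupancy | run-all`); exit codes are 0 (success), 2 (usage/config),
3 (data validation), 4 (numerical failure).

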