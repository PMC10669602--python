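# Methods

## The exchange process and its two observables

F₁-ATPase hydrolyzes MgATP at three β-catalytic sites. While phosphate
(or the γ-phosphoryl of bound ATP) resides in a catalytic site, its
oxygen ligands exchange with water oxygens; released Pi therefore
carries a record of how long, and at how many sites, the exchange ran.
Two labeling configurations probe the same process:

* **Uptake** — label in water (H¹⁸OH). The observable is the mean
  labeled-oxygen count of released Pi, ¹⁸O/P ∈ [0, 4], equivalently the
  fractional extent X = ¹⁸O/P ⁄ 4. Exactly one of the four Pi oxygens
  is delivered by the water consumed in bond cleavage, so X starts at
  X_i = 1/4 and relaxes toward 1 as X = 1 − 0.75 e^(−kt). The extent is
  the same whether exchange happens before or after the cleavage step
  (the weighted-sum identity (3/4)(1 − e^(−kt)) + 1/4); the package
  exposes both forms and tests their equality.
* **Washout** — label on the γ-phosphoryl of substrate ATP. The
  observable is the GC-MS isotopomer distribution (percent of Pi with
  3, 2, 1, 0 labels). Labels are lost one at a time at a constant event
  rate, so the event count over time t is Poisson(kt) and the
  closed-form solutions of the series chain apply, with the zero-label
  pool obtained by normalization closure (the chain is absorbing at 0;
  no ¹⁸O₄ state exists, since at most three labels originate from the
  γ-phosphoryl).

Everything is parameterized by the dimensionless product kt. The
exchange time at one site over one catalytic cycle is the reciprocal
steady-state velocity 1/v; n sites exchanging simultaneously give
t = n/v. Distributions are stored on the percentage scale used in GC-MS
reports; internal arithmetic uses fractions.

## Parameters

| parameter | meaning | unit | default | origin |
|---|---|---|---|---|
| k | apparent rate constant of exchange events | s⁻¹ | 10.5 | measured constant of the mitochondrial enzyme, recovered by the package's own fit |
| n | simultaneously exchanging catalytic sites | — | regime rule | 3 below 33 ms per-cycle time, 2 above |
| X_i | initial labeled fraction of Pi | — | 0.25 | hydrolysis stoichiometry (one water oxygen per Pi) |
| V_max, K_m | Michaelis–Menten constants for velocity | s⁻¹, µM | 640, 99 | measured for the mitochondrial enzyme |
| K_d1–K_d3 | site dissociation constants | µM | (0.018, 1, 150) MF₁; (0.02, 1.4, K_m) EF₁-style | published binding measurements; K_d3 ≅ K_m stand-in provided as a constructor |
| initial distribution | γ-phosphoryl label percentages | % | 57/17/2/24 | measured substrate composition |
| molecules/condition | simulated GC-MS sample size | — | 10⁴ | gives percentage scatter comparable to reported error bars |

## Estimation and selection

**Rate constant.** Ordinary least squares of y = ln[0.75/(1 − X)] on
t = 1/v with the intercept fixed at zero, since the law has none; R² is
computed about the origin in this mode. A free-intercept mode exists for
diagnostics and then reports conventional R². The fit is unweighted (no
per-point uncertainties are assumed available). Two numerical guards:
extents within 10⁻¹² of 1 are clamped before the log (a measured ¹⁸O/P
of 3.98 is near-singular but informative), while extents beyond a
caller-supplied dynamic-range limit `max_extent` are excluded with a
warning — a finite sample of N molecules cannot resolve 1 − X below
~1/(4N), and a clamped saturated point would enter the regression as an
unbounded outlier. The pipeline passes 1 − 10/(4N) when it knows the
simulated molecule count; for real tables the default excludes only the
clamp boundary itself.

**Site count.** For each candidate n ∈ {1, 2, 3} the washout prediction
at kt = k·n/v is compared with the measured distribution by the sum of
squared differences over the four percentage components; the argmin is
selected, ties break toward smaller n (parsimony) and are flagged. A
Pearson χ²-on-counts criterion is available behind a flag when the
molecule count is known. Selection consistency (accuracy → 1 as the
molecule count grows) is verified in the test suite.

**Transition.** Observations are ordered by 1/v; the transition time is
the midpoint between the longest time labeled n = 3 and the shortest
labeled n = 2, with the bracketing ATP concentrations reported. A
non-monotone label sequence is a warning, not an error — single
misselections near the noise floor should not abort an analysis.

**Michaelis–Menten.** Nonlinear least squares of v = V_max S/(K_m + S)
(scipy `curve_fit`), initialized from the double-reciprocal
linearization; a saturated design (all S ≫ K_m) shows up as a K_m
standard error comparable to the estimate.

**Occupancy.** The default binding model treats the three sites as
independent with site-specific K_d, i.e. the grand partition function
over all 8 occupancy patterns: this is required for mixed bisite
species such as (101) and (011) to exist at all. A strictly sequential
(ordered Adair) mode is provided for sensitivity analysis. MgATP is the
only ligand modeled; MgADP competition is out of scope (no constants
available). Equilibrium occupancy only — no kinetic occupancy dynamics.

## The simulator and what it does (not) emulate

`simulate_dataset` generates, per ATP concentration: the
Michaelis–Menten velocity, the per-cycle time 1/v, the site count from
the 33 ms hard-threshold rule, and then both observables — an uptake
¹⁸O/P (each Pi carries 1 + Binomial(3, 1 − e^(−kt)) labels, kt = k/v)
and a washout isotopomer distribution (multinomial start from the
initial distribution, Poisson(k·n/v) label loss per molecule).
Measurement noise is purely multinomial counting of a finite molecule
number; everything is driven by one `numpy` Generator, so a fixed seed
reproduces the dataset bit-for-bit. The general state-dependent-rate
chain is available (`simulate_molecule_washout_general`) for sensitivity
studies; with equal rates it reduces to the Poisson chain, which the
tests verify.

Not emulated: instrument drift or peak-integration error in the GC-MS
channel, replicate-level (between-run) variance, rotary dwell structure,
any smooth crossover of the site-count rule, and ¹⁸O₄ species. Passing
recovery tests on this generator therefore demonstrates correctness of
the estimators under idealized counting noise, not robustness to
systematic measurement error in real chromatograms.

## Numerical choices and degenerate inputs

* kt is always the composite argument; functions taking (k, n, v)
  compute kt = k·n/v once, so the n factor cannot be double-counted.
* The washout closed forms are evaluated through a 4×4 transition
  matrix whose last column closes the normalization, keeping component
  sums at exactly 100 despite rounding.
* kt = 0 is the identity everywhere; a no-exchange observation makes
  all site counts equivalent, which the selector reports as a tie
  resolved to n = 1.
* The uptake round trip kt → X → kt is exact to 1e-10 only while 1 − X
  is representable: storing X as a double leaves an irreducible error
  ~ε·e^(kt), and the 1 − 10⁻¹² clamp saturates the inverse at
  kt ≈ 27.3. The property tests carry this floating-point bound.
* Observation tables tolerate percentage-rounding up to ±0.5 per row
  (renormalized on ingest) and a trace p4 channel ≤ 0.5 %.
* Simulation sizes in the test suite: 10⁶ molecules for closed-form vs
  Monte-Carlo oracle agreement (3 SE bands), 10⁵ for chi-square
  goodness-of-fit (α = 10⁻³) and for transition-bracket recovery, 10⁴ —
  the generator default — for the study-condition recovery checks
  (rate constant within 5 %, pooled site-count accuracy ≥ 95 % over 100
  seeds). Bracket recovery uses 10⁵ because at the highest ATP
  concentrations the spacing between candidate predictions (~1
  percentage point on the triple-labeled component) is only ~2 SD of
  counting noise at 10⁴, so occasional misselections would invert the
  bracket; the larger sample isolates the property being tested.

## Known limitations

* The same k enters the per-oxygen uptake law and the per-molecule
  washout chain; these correspond to different microscopic pictures
  (independent oxygens vs a single event chain). The package follows
  that convention literally and does not attempt a reconciliation.
* A washout mean can only decrease from the initial 2.07 labels/Pi, so
  a measured ¹⁸O/P above it in washout convention is measurement
  scatter; the consistency check between a distribution and its mean is
  scoped to the washout convention and carries a configurable tolerance.
* The zero-intercept choice for the rate-constant fit is the model's;
  whether a free intercept would change a given dataset's estimate is
  left to the diagnostic mode.
* Occupancy curves are equilibrium-only and single-ligand; they are not
  intended to reproduce any particular published curve point-for-point.
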