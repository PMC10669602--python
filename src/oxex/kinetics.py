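"""Closed-form kinetics of intermediate Pi-HOH oxygen exchange.

During ATP hydrolysis by F1-ATPase, oxygen atoms of enzyme-bound Pi (or of
the gamma-phosphoryl of bound ATP) exchange with water oxygens before the
Pi is released.  Two experimental configurations are covered:

* **uptake** — label initially in water; the fractional extent of exchange
  X (fraction of the four Pi oxygens that are labeled) grows from the
  hydrolytic baseline ``Xi = 1/4`` as ``X = 1 - (1 - Xi) * exp(-k*t)``,
  i.e. ``ln[(1 - Xi)/(1 - X)] = k*t``.  One of the four Pi oxygens always
  comes from a water molecule consumed by the hydrolysis step itself,
  which fixes the initial condition at one part in four.

* **washout** — label initially on the gamma-phosphoryl of ATP; the
  population of Pi species carrying 3, 2, 1, 0 labels evolves as a
  constant-rate event chain (a Poisson process per molecule), for which
  the 3-, 2- and 1-label pools have closed forms and the 0-label pool
  closes the normalization to 100 %.

All operations are written in terms of the dimensionless product ``kt``
(apparent exchange rate constant times per-site exchange time); callers
holding a velocity obtain the time from :func:`per_site_time`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HYDROLYSIS_XI",
    "LabelDistribution",
    "FractionalExtent",
    "ExchangeModel",
    "extent_from_kt",
    "kt_from_extent",
    "extent_prehydrolysis_pathway",
    "extent_to_o18_per_p",
    "o18_per_p_to_extent",
    "per_site_time",
    "isotopomer_distribution",
    "mean_label_count",
    "initial_fraction_from_stoichiometry",
]

#: Oxygens a Pi molecule carries, and how many of them derive from the
#: water consumed by the bond-cleavage step (one per hydrolysis event).
_OXYGENS_PER_PI = 4
_WATER_OXYGENS_PER_HYDROLYSIS = 1

# X values this close to 1 are clamped before the log transform; measured
# 18O/P near 4 (e.g. 3.98) would otherwise blow up the inverse.
_X_CLAMP = 1.0 - 1e-12


def initial_fraction_from_stoichiometry() -> float:
    """Initial labeled fraction of Pi set by hydrolysis stoichiometry.

    Exactly one of the four oxygens of each released Pi is incorporated
    from medium water by the cleavage reaction itself, so in the uptake
    configuration the extent of exchange starts at 1/4 before any
    exchange event has occurred.
    """
    return _WATER_OXYGENS_PER_HYDROLYSIS / _OXYGENS_PER_PI


HYDROLYSIS_XI: float = initial_fraction_from_stoichiometry()


@dataclass(frozen=True)
class LabelDistribution:
    """Percentages of Pi (or gamma-phosphoryl) species with 3..0 labels.

    Components are on the 0-100 scale used by GC-MS reports and must sum
    to 100 within a relative 1e-9.  Measured tables with rounding error
    should go through :meth:`from_measured`, which renormalizes.
    """

    p3: float
    p2: float
    p1: float
    p0: float

    def __post_init__(self) -> None:
        comps = (self.p3, self.p2, self.p1, self.p0)
        if any(not math.isfinite(c) for c in comps):
            raise ValueError(f"non-finite component in {comps}")
        if any(c < 0 for c in comps):
            raise ValueError(f"negative component in {comps}")
        total = sum(comps)
        if not math.isclose(total, 100.0, rel_tol=1e-9):
            raise ValueError(
                f"components sum to {total!r}, expected 100 (rel tol 1e-9)"
            )

    @classmethod
    def from_measured(
        cls, p3: float, p2: float, p1: float, p0: float, tol: float = 0.5
    ) -> "LabelDistribution":
        """Build from measured percentages, tolerating rounding up to *tol*."""
        total = p3 + p2 + p1 + p0
        if abs(total - 100.0) > tol:
            raise ValueError(
                f"measured percentages sum to {total}, outside 100 +/- {tol}"
            )
        scale = 100.0 / total
        return cls(p3 * scale, p2 * scale, p1 * scale, p0 * scale)

    @classmethod
    def from_counts(cls, counts) -> "LabelDistribution":
        """Percentage distribution from raw molecule counts (n3, n2, n1, n0)."""
        arr = np.asarray(counts, dtype=float)
        if arr.shape != (4,) or arr.sum() <= 0:
            raise ValueError("counts must be four non-negative numbers, sum > 0")
        pct = 100.0 * arr / arr.sum()
        return cls(*pct)

    def as_array(self) -> np.ndarray:
        """Components ordered (p3, p2, p1, p0) on the percentage scale."""
        return np.array([self.p3, self.p2, self.p1, self.p0])


@dataclass(frozen=True)
class FractionalExtent:
    """Fractional extent of exchange X and the equivalent mean 18O/P = 4X."""

    X: float
    o18_per_p: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.X <= 1.0:
            raise ValueError(f"extent X={self.X} outside [0, 1]")
        object.__setattr__(self, "o18_per_p", _OXYGENS_PER_PI * self.X)


@dataclass(frozen=True)
class ExchangeModel:
    """Apparent exchange rate constant, site count and initial extent.

    Parameters
    ----------
    k : float
        Apparent first-order rate constant of exchange events, s^-1.
    n : int
        Number of catalytic sites simultaneously mediating exchange; the
        per-site exchange time is ``n / velocity``.
    xi : float
        Initial labeled fraction of Pi in the uptake configuration.
    """

    k: float
    n: int = 1
    xi: float = HYDROLYSIS_XI

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"rate constant k={self.k} must be positive")
        if self.n not in (1, 2, 3):
            raise ValueError(f"site count n={self.n} must be 1, 2 or 3")
        if not 0.0 <= self.xi < 1.0:
            raise ValueError(f"initial fraction xi={self.xi} outside [0, 1)")

    def kt(self, velocity: float) -> float:
        """Dimensionless exchange progress k * (n / velocity)."""
        return self.k * per_site_time(velocity, self.n)

    def extent_at_velocity(self, velocity: float) -> FractionalExtent:
        return extent_from_kt(self.kt(velocity), self.xi)

    def distribution_at_velocity(
        self, initial: LabelDistribution, velocity: float
    ) -> LabelDistribution:
        return isotopomer_distribution(initial, self.kt(velocity))


def extent_from_kt(kt: float, xi: float = HYDROLYSIS_XI) -> FractionalExtent:
    """Extent of exchange after dimensionless progress *kt*.

    Solves dX/dt = k (1 - X) with X(0) = xi:  X = 1 - (1 - xi) exp(-kt).
    """
    if kt < 0:
        raise ValueError(f"kt={kt} must be non-negative")
    if not 0.0 <= xi < 1.0:
        raise ValueError(f"xi={xi} outside [0, 1)")
    return FractionalExtent(1.0 - (1.0 - xi) * math.exp(-kt))


def kt_from_extent(X: float) -> float:
    """Invert the uptake law for the hydrolysis initial condition.

    kt = ln[0.75 / (1 - X)], defined for X in [0.25, 1).  Values within
    1e-12 of 1 are clamped (with a log record) so that near-saturating
    measurements (18O/P -> 4) do not produce infinities.
    """
    if X < HYDROLYSIS_XI:
        raise ValueError(
            f"extent X={X} below the hydrolytic floor {HYDROLYSIS_XI}; "
            "would imply negative exchange time"
        )
    if X >= 1.0:
        raise ValueError(f"extent X={X} must be < 1")
    if X > _X_CLAMP:
        logger.warning("clamping near-saturated extent X=%r before log", X)
        X = _X_CLAMP
    return math.log((1.0 - HYDROLYSIS_XI) / (1.0 - X))


def extent_prehydrolysis_pathway(kt: float) -> FractionalExtent:
    """Extent when exchange on the gamma-phosphoryl precedes hydrolysis.

    Three quarters of the label arrives through pre-hydrolysis exchange,
    X_A = 1 - exp(-kt), and one quarter through the water oxygen fixed by
    the cleavage step: X = (3/4)(1 - exp(-kt)) + 1/4.  Identical to
    :func:`extent_from_kt` at xi = 1/4 — the observable extent does not
    depend on the order of exchange and hydrolysis.
    """
    if kt < 0:
        raise ValueError(f"kt={kt} must be non-negative")
    x_pre = 1.0 - math.exp(-kt)
    return FractionalExtent(0.75 * x_pre + 0.25)


def extent_to_o18_per_p(X: float) -> float:
    """Mean labeled oxygens per Pi for extent *X* (simply 4X)."""
    if not 0.0 <= X <= 1.0:
        raise ValueError(f"extent X={X} outside [0, 1]")
    return _OXYGENS_PER_PI * X


def o18_per_p_to_extent(o18_per_p: float) -> float:
    """Extent X from a mean 18O/P measurement (X = 18O/P / 4)."""
    if not 0.0 <= o18_per_p <= _OXYGENS_PER_PI:
        raise ValueError(f"18O/P={o18_per_p} outside [0, {_OXYGENS_PER_PI}]")
    return o18_per_p / _OXYGENS_PER_PI


def per_site_time(velocity: float, n: int = 1) -> float:
    """Exchange time available at *n* simultaneously exchanging sites.

    The time base is the reciprocal of the steady-state hydrolysis
    velocity (one catalytic cycle); n sites exchanging at once multiply
    the effective time by n.
    """
    if velocity <= 0:
        raise ValueError(f"velocity={velocity} must be positive")
    if n not in (1, 2, 3):
        raise ValueError(f"site count n={n} must be 1, 2 or 3")
    return n / velocity


def _washout_matrix(kt: float) -> np.ndarray:
    """Transition matrix M with M[i, j] = P(start with i labels -> end with j).

    Labels are lost one at a time at constant rate, so the number of loss
    events in time t is Poisson(kt) and the chain is absorbing at zero.
    Row/column order matches LabelDistribution: (3, 2, 1, 0) labels.
    """
    e = math.exp(-kt)
    p0 = e                      # zero events
    p1 = kt * e                 # one event
    p2 = kt * kt * e / 2.0      # two events
    m = np.zeros((4, 4))
    m[0] = [p0, p1, p2, 1.0 - p0 - p1 - p2]   # start with 3 labels
    m[1] = [0.0, p0, p1, 1.0 - p0 - p1]       # start with 2
    m[2] = [0.0, 0.0, p0, 1.0 - p0]           # start with 1
    m[3] = [0.0, 0.0, 0.0, 1.0]               # 0 labels: absorbing
    return m


def isotopomer_distribution(
    initial: LabelDistribution, kt: float
) -> LabelDistribution:
    """Washout of the label distribution after dimensionless progress *kt*.

    Closed-form solution of the constant-rate series chain
    A1 -> A2 -> A3 -> A4 (3 -> 2 -> 1 -> 0 labels):

    * p3(kt) = p3(0) e^-kt
    * p2(kt) = p3(0) kt e^-kt + p2(0) e^-kt
    * p1(kt) = p3(0) (kt)^2 e^-kt / 2 + p2(0) kt e^-kt + p1(0) e^-kt
    * p0(kt) = 100 - p3 - p2 - p1   (normalization closure)
    """
    if kt < 0:
        raise ValueError(f"kt={kt} must be non-negative")
    evolved = initial.as_array() @ _washout_matrix(kt)
    # closure keeps the sum at exactly 100 despite rounding
    p3, p2, p1 = evolved[:3]
    return LabelDistribution(p3, p2, p1, 100.0 - p3 - p2 - p1)


def mean_label_count(dist: LabelDistribution) -> float:
    """Mean number of labels per Pi (0-3) carried by a distribution."""
    return (3.0 * dist.p3 + 2.0 * dist.p2 + 1.0 * dist.p1) / 100.0
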