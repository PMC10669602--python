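"""Parameter estimation and model selection for oxygen-exchange data.

The estimation flow mirrors how the exchange experiments are analyzed:
the apparent rate constant k comes from a zero-intercept regression of
the log-transformed extent on the exchange time (the uptake law has no
intercept), the number of simultaneously exchanging sites n is selected
per observation by least-squares comparison of predicted isotopomer
distributions, and a Michaelis-Menten fit of (ATP, velocity) pairs
supplies Vmax and Km for activity normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .kinetics import (
    HYDROLYSIS_XI,
    LabelDistribution,
    isotopomer_distribution,
    kt_from_extent,
    mean_label_count,
    o18_per_p_to_extent,
    per_site_time,
)

__all__ = [
    "ExchangeObservation",
    "FitResult",
    "SiteCountSelection",
    "TransitionResult",
    "fit_rate_constant",
    "select_site_count",
    "detect_transition",
    "fit_michaelis_menten",
]


@dataclass(frozen=True)
class ExchangeObservation:
    """One experimental condition of the exchange assay.

    Parameters
    ----------
    velocity : float
        Steady-state hydrolysis velocity, mol Pi (mol F1)^-1 s^-1.
    atp_conc : float, optional
        Medium ATP concentration, uM.
    o18_per_p : float, optional
        Mean labeled oxygens per released Pi (0-4).
    distribution : LabelDistribution, optional
        Measured isotopomer percentages.
    convention : str
        Which labeling configuration *o18_per_p* refers to: ``"washout"``
        (label on the gamma-phosphoryl, washed into unlabeled water),
        ``"uptake"`` (label in water, taken up into Pi) or ``"mixed"``
        (uptake 18O/P paired with a washout distribution, as when both
        experimental configurations were run at the same condition).

    At least one of *o18_per_p* / *distribution* must be present.  When
    both are given in the washout configuration they describe the same
    sample, so their means must agree within *consistency_tol* labels;
    in the other conventions they are independent measurements.
    """

    velocity: float
    atp_conc: float | None = None
    o18_per_p: float | None = None
    distribution: LabelDistribution | None = None
    convention: str = "washout"
    consistency_tol: float = 0.25

    def __post_init__(self) -> None:
        if self.convention not in ("washout", "uptake", "mixed"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.velocity <= 0:
            raise ValueError(f"velocity={self.velocity} must be positive")
        if self.atp_conc is not None and self.atp_conc <= 0:
            raise ValueError(f"atp_conc={self.atp_conc} must be positive")
        if self.o18_per_p is None and self.distribution is None:
            raise ValueError(
                "observation needs o18_per_p or an isotopomer distribution"
            )
        if self.o18_per_p is not None and not 0.0 <= self.o18_per_p <= 4.0:
            raise ValueError(f"o18_per_p={self.o18_per_p} outside [0, 4]")
        if (
            self.convention == "washout"
            and self.o18_per_p is not None
            and self.distribution is not None
            and abs(mean_label_count(self.distribution) - self.o18_per_p)
            > self.consistency_tol
        ):
            raise ValueError(
                "o18_per_p and distribution disagree: "
                f"{self.o18_per_p} vs {mean_label_count(self.distribution):.3f}"
            )

    def hydrolysis_time(self) -> float:
        """Per-cycle time 1/v, the x-axis of the rate-constant fit."""
        return per_site_time(self.velocity, 1)


@dataclass(frozen=True)
class FitResult:
    """Point estimates with standard errors, R^2 and residuals."""

    estimates: dict
    standard_errors: dict
    r_squared: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if set(self.estimates) != set(self.standard_errors):
            raise ValueError("estimates and standard_errors name different parameters")


@dataclass(frozen=True)
class SiteCountSelection:
    """Outcome of the per-observation site-count scan."""

    n: int
    sse: dict[int, float]
    tie: bool = False


@dataclass(frozen=True)
class TransitionResult:
    """Location of the n-regime change along the exchange-time axis."""

    found: bool
    transition_time: float | None = None
    bracket_times: tuple[float, float] | None = None
    bracket_atp: tuple[float | None, float | None] | None = None
    labels: tuple[int, ...] = field(default_factory=tuple)


def _extent_of(obs: ExchangeObservation) -> float:
    if obs.o18_per_p is not None:
        return o18_per_p_to_extent(obs.o18_per_p)
    return mean_label_count(obs.distribution) / 4.0  # pragma: no cover


def fit_rate_constant(
    observations: list[ExchangeObservation],
    n: int = 1,
    fit_intercept: bool = False,
    max_extent: float = 1.0 - 1e-12,
) -> FitResult:
    """Estimate the apparent exchange rate constant k.

    Regresses y = ln[(1 - Xi)/(1 - X)] on the exchange time t = n/v.
    The uptake law passes through the origin, so the default is a
    zero-intercept fit with R^2 computed about the origin; a free
    intercept is available for diagnostics and then reports the
    conventional R^2.

    Observations whose extent exceeds *max_extent* sit beyond the
    measurement's dynamic range (the log transform is unbounded as
    X -> 1) and are excluded with a warning.  Callers that know the
    molecule count N of the assay should pass ``1 - c/(4N)`` for a small
    count c of resolvable unlabeled oxygens.

    Raises
    ------
    ValueError
        If fewer than two usable observations remain, if any extent
        falls below the hydrolytic floor X = 0.25, or if the design is
        singular (all times equal, intercept mode).
    """
    usable = [o for o in observations if o.o18_per_p is not None]
    if len(usable) < 2:
        raise ValueError("need >= 2 observations with velocity and o18_per_p")
    for i, obs in enumerate(usable):
        if _extent_of(obs) < HYDROLYSIS_XI:
            raise ValueError(
                f"observation {i} (velocity={obs.velocity}) has extent "
                f"{_extent_of(obs):.4f} < {HYDROLYSIS_XI}; 18O/P must be >= 1"
            )
    saturated = [o for o in usable if _extent_of(o) > max_extent]
    if saturated:
        warnings.warn(
            f"excluding {len(saturated)} saturated observation(s) with "
            f"extent > {max_extent}",
            stacklevel=2,
        )
        usable = [o for o in usable if _extent_of(o) <= max_extent]
    if len(usable) < 2:
        raise ValueError("fewer than 2 observations below the saturation limit")
    t = np.array([per_site_time(o.velocity, n) for o in usable])
    y = np.array([kt_from_extent(_extent_of(o)) for o in usable])

    if fit_intercept:
        if np.ptp(t) == 0:
            raise ValueError("singular design: all exchange times equal")
        design = np.column_stack([t, np.ones_like(t)])
        names = ("k", "intercept")
    else:
        design = t[:, None]
        names = ("k",)

    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    dof = max(len(y) - len(names), 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    if fit_intercept:
        tss = float(np.sum((y - y.mean()) ** 2))
    else:
        tss = float(y @ y)  # R^2 about the origin for the no-intercept law
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return FitResult(
        estimates=dict(zip(names, coef.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        r_squared=r2,
        residuals=resid,
    )


def select_site_count(
    obs: ExchangeObservation,
    k: float,
    initial: LabelDistribution,
    candidates: tuple[int, ...] = (1, 2, 3),
    criterion: str = "sse",
    molecules: int | None = None,
) -> SiteCountSelection:
    """Choose the site count whose predicted distribution best matches *obs*.

    For each candidate n the washout prediction at kt = k * n / v is
    compared with the measured isotopomer percentages.  The default
    criterion is the sum of squared differences over the four percentage
    components; ``criterion="chi2"`` instead uses Pearson chi-square on
    counts (requires *molecules*, the number of molecules measured).
    Ties break toward smaller n (parsimony) and are flagged.
    """
    if not candidates:
        raise ValueError("candidate site-count set is empty")
    if k <= 0:
        raise ValueError(f"rate constant k={k} must be positive")
    if obs.distribution is None:
        raise ValueError(
            "site-count selection needs a measured isotopomer distribution; "
            "this observation carries only 18O/P"
        )
    if criterion not in ("sse", "chi2"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "chi2" and not molecules:
        raise ValueError("chi2 criterion needs the molecule count")

    measured = obs.distribution.as_array()
    scores: dict[int, float] = {}
    for n in sorted(candidates):
        predicted = isotopomer_distribution(
            initial, k * per_site_time(obs.velocity, n)
        ).as_array()
        if criterion == "sse":
            scores[n] = float(np.sum((measured - predicted) ** 2))
        else:
            expected = np.maximum(predicted / 100.0 * molecules, 1e-12)
            observed = measured / 100.0 * molecules
            scores[n] = float(np.sum((observed - expected) ** 2 / expected))
    best = min(scores, key=lambda n: (scores[n], n))
    tie = any(
        np.isclose(scores[n], scores[best], rtol=1e-12, atol=1e-12)
        for n in scores
        if n != best
    )
    if tie:
        best = min(n for n in scores if np.isclose(scores[n], scores[best]))
    return SiteCountSelection(n=best, sse=scores, tie=tie)


def detect_transition(
    observations: list[ExchangeObservation],
    k: float,
    initial: LabelDistribution,
    candidates: tuple[int, ...] = (2, 3),
) -> TransitionResult:
    """Locate the change from three to two simultaneously exchanging sites.

    Observations are ordered by hydrolysis time 1/v (short times = high
    ATP).  Each is labeled by :func:`select_site_count`; the transition
    time is the midpoint between the longest time labeled n=3 and the
    shortest labeled n=2.  A non-monotone label sequence (n rising with
    time) is reported as a warning alongside the full label vector.
    """
    if len(observations) < 2:
        raise ValueError("need >= 2 observations to locate a transition")
    ordered = sorted(observations, key=lambda o: o.hydrolysis_time())
    labels = tuple(
        select_site_count(o, k, initial, candidates).n for o in ordered
    )
    if any(b > a for a, b in zip(labels, labels[1:])):
        warnings.warn(
            f"site-count labels are not monotone along time: {labels}",
            stacklevel=2,
        )
    times = [o.hydrolysis_time() for o in ordered]
    t3 = [t for t, n in zip(times, labels) if n == 3]
    t2 = [t for t, n in zip(times, labels) if n == 2]
    if not t3 or not t2:
        return TransitionResult(found=False, labels=labels)
    lo, hi = max(t3), min(t2)
    atp_of = {o.hydrolysis_time(): o.atp_conc for o in ordered}
    return TransitionResult(
        found=True,
        transition_time=0.5 * (lo + hi),
        bracket_times=(lo, hi),
        bracket_atp=(atp_of[lo], atp_of[hi]),
        labels=labels,
    )


def fit_michaelis_menten(concentrations, velocities) -> FitResult:
    """Nonlinear least-squares fit of v = Vmax * S / (Km + S).

    Initial guesses come from the double-reciprocal linearization.  A Km
    standard error comparable to the estimate itself signals an
    unidentifiable design (all S far above Km).
    """
    S = np.asarray(concentrations, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if S.shape != v.shape or S.size < 3:
        raise ValueError("need >= 3 matched (S, v) pairs")
    if np.any(S <= 0) or np.any(v <= 0):
        raise ValueError("concentrations and velocities must be positive")

    # Lineweaver-Burk start: 1/v = (Km/Vmax)(1/S) + 1/Vmax
    slope, icept = np.polyfit(1.0 / S, 1.0 / v, 1)
    if icept <= 0:  # saturated or noisy design; fall back to crude guesses
        vmax0, km0 = float(v.max()) * 1.05, float(np.median(S))
    else:
        vmax0, km0 = 1.0 / icept, max(slope / icept, S.min() * 1e-3)

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    try:
        popt, pcov = optimize.curve_fit(
            mm, S, v, p0=[vmax0, km0], maxfev=10000
        )
    except RuntimeError as err:  # pragma: no cover - scipy convergence failure
        raise ValueError(f"Michaelis-Menten fit did not converge: {err}") from err
    resid = v - mm(S, *popt)
    rss = float(resid @ resid)
    tss = float(np.sum((v - v.mean()) ** 2))
    se = np.sqrt(np.diag(pcov))
    return FitResult(
        estimates={"vmax": float(popt[0]), "km": float(popt[1])},
        standard_errors={"vmax": float(se[0]), "km": float(se[1])},
        r_squared=1.0 - rss / tss if tss > 0 else 1.0,
        residuals=resid,
    )
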