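"""Observation tables, run configuration, and the end-to-end pipeline.

The on-disk observation format is a plain delimited table (comma by
default, tab accepted) with one row per experimental condition.  All
columns are named; percentages are stored on the printed 0-100 scale.

Required columns: ``atp_conc_uM``, ``velocity_per_s``.
Optional columns: ``o18_per_p``, ``p3_pct``, ``p2_pct``, ``p1_pct``,
``p0_pct``, ``p4_pct``.  Percentage columns, when present, must sum to
100 +/- 0.5 per row (measurement rounding); a ``p4_pct`` channel is
accepted because the GC-MS assay monitors it, but the exchange theory
has no four-label state, so it must be ~0.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    ExchangeObservation,
    detect_transition,
    fit_michaelis_menten,
    fit_rate_constant,
    select_site_count,
)
from .kinetics import LabelDistribution
from .occupancy import (
    BindingModel,
    bisite_activity_fraction,
    normalized_activity,
    trisite_activity_fraction,
)
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "DataValidationError",
    "ConfigError",
    "RunConfig",
    "read_observations",
    "write_observations",
    "run_pipeline",
]

_REQUIRED_COLUMNS = ("atp_conc_uM", "velocity_per_s")
_PCT_COLUMNS = ("p3_pct", "p2_pct", "p1_pct", "p0_pct")
_OPTIONAL_COLUMNS = ("o18_per_p", *_PCT_COLUMNS, "p4_pct")
_PCT_SUM_TOL = 0.5
_P4_TOL = 0.5


class DataValidationError(ValueError):
    """An observations table failed a structural or row-level check."""


class ConfigError(ValueError):
    """A run configuration is malformed."""


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in header else ","


def read_observations(
    path, convention: str = "washout"
) -> list[ExchangeObservation]:
    """Parse a delimited observations table into validated records.

    *convention* states which labeling configuration the ``o18_per_p``
    column refers to (see :class:`~oxex.inference.ExchangeObservation`).
    Errors name the offending row (1-based, excluding the header) and
    column.
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"observations file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=_sniff_sep(path))
    except Exception as err:
        raise DataValidationError(f"cannot parse {path}: {err}") from err
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")
    unknown = [
        c
        for c in frame.columns
        if c not in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS
    ]
    if unknown:
        raise DataValidationError(f"{path}: unknown columns {unknown}")
    if frame.empty:
        raise DataValidationError(f"{path}: table has no data rows")

    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna()
        if col == "o18_per_p":  # the one column where blanks are meaningful
            bad &= ~frame[col].isna()
        if bad.any():
            raise DataValidationError(
                f"{path}: non-numeric value in column {col!r}, row "
                f"{int(frame.index[bad.argmax()]) + 1}"
            )
    has_dist = all(c in frame.columns for c in _PCT_COLUMNS)

    observations = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 1
        dist = None
        if has_dist:
            pcts = [float(row[c]) for c in _PCT_COLUMNS]
            p4 = float(row["p4_pct"]) if "p4_pct" in frame.columns else 0.0
            if p4 > _P4_TOL:
                raise DataValidationError(
                    f"{path}: row {rownum}: p4_pct={p4} exceeds {_P4_TOL}; "
                    "the exchange model has no four-label Pi species"
                )
            total = sum(pcts) + p4
            if abs(total - 100.0) > _PCT_SUM_TOL:
                raise DataValidationError(
                    f"{path}: row {rownum}: percentage columns sum to "
                    f"{total}, outside 100 +/- {_PCT_SUM_TOL}"
                )
            dist = LabelDistribution.from_measured(*pcts, tol=_PCT_SUM_TOL + p4)
        o18 = (
            float(row["o18_per_p"])
            if "o18_per_p" in frame.columns and not pd.isna(row["o18_per_p"])
            else None
        )
        try:
            observations.append(
                ExchangeObservation(
                    velocity=float(row["velocity_per_s"]),
                    atp_conc=float(row["atp_conc_uM"]),
                    o18_per_p=o18,
                    distribution=dist,
                    convention=convention,
                )
            )
        except ValueError as err:
            raise DataValidationError(f"{path}: row {rownum}: {err}") from err
    return observations


def write_observations(observations, path, sep: str = ",") -> None:
    """Write records back to a delimited table in canonical formatting.

    Canonical means: fixed column order, 17-significant-digit floats, so
    that a write/read/write cycle is byte-identical.
    """
    rows = []
    for obs in observations:
        row: dict[str, Any] = {
            "atp_conc_uM": obs.atp_conc,
            "velocity_per_s": obs.velocity,
            "o18_per_p": obs.o18_per_p,
        }
        if obs.distribution is not None:
            d = obs.distribution
            row.update(
                p3_pct=d.p3, p2_pct=d.p2, p1_pct=d.p1, p0_pct=d.p0
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration for :func:`run_pipeline`.

    Exactly one of *observations_path* / *simulation* supplies the data.
    A fixed *k* (s^-1) skips the rate-constant fit; fixed *vmax*/*km*
    (s^-1, uM) skip the Michaelis-Menten fit.  *kd_sets* maps curve
    names to (kd1, kd2, kd3) in uM for the occupancy stage.
    """

    seed: int = 0
    observations_path: str | None = None
    simulation: SimulationConfig | None = None
    convention: str = "mixed"
    k: float | None = None
    initial: LabelDistribution | None = None
    candidates: tuple[int, ...] = (1, 2, 3)
    kd_sets: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=dict
    )
    vmax: float | None = None
    km: float | None = None

    _KEYS = (
        "seed",
        "observations_path",
        "simulation",
        "convention",
        "k",
        "initial",
        "candidates",
        "kd_sets",
        "vmax",
        "km",
    )

    def __post_init__(self) -> None:
        if (self.observations_path is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of observations_path / simulation must be set"
            )
        if self.k is not None and self.k <= 0:
            raise ConfigError(f"k={self.k} must be positive")
        for name in ("vmax", "km"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ConfigError(f"{name}={val} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a JSON or YAML config document; unknown keys are rejected."""
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        try:
            doc = (
                json.loads(text)
                if path.suffix == ".json"
                else yaml.safe_load(text)
            )
        except Exception as err:
            raise ConfigError(f"cannot parse {path}: {err}") from err
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config document must be a mapping")
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - set(cls._KEYS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        if "initial" in doc and doc["initial"] is not None:
            vals = doc["initial"]
            if not (isinstance(vals, (list, tuple)) and len(vals) == 4):
                raise ConfigError("initial must be four percentages [p3,p2,p1,p0]")
            doc["initial"] = LabelDistribution.from_measured(*vals)
        if "candidates" in doc:
            doc["candidates"] = tuple(int(n) for n in doc["candidates"])
        if "kd_sets" in doc and doc["kd_sets"] is not None:
            doc["kd_sets"] = {
                str(name): tuple(float(x) for x in kds)
                for name, kds in doc["kd_sets"].items()
            }
        if "simulation" in doc and doc["simulation"] is not None:
            sim = dict(doc["simulation"])
            if "initial" in sim:
                sim["initial"] = LabelDistribution.from_measured(*sim["initial"])
            if "atp_concs" in sim:
                sim["atp_concs"] = tuple(float(s) for s in sim["atp_concs"])
            try:
                doc["simulation"] = SimulationConfig(**sim)
            except (TypeError, ValueError) as err:
                raise ConfigError(f"invalid simulation block: {err}") from err
        try:
            return cls(**doc)
        except TypeError as err:
            raise ConfigError(str(err)) from err


def _occupancy_table(kd_sets, atp_grid) -> list[dict]:
    rows = []
    for name, kds in kd_sets.items():
        model = BindingModel(*kds)
        tri = trisite_activity_fraction(atp_grid, model)
        bi = bisite_activity_fraction(atp_grid, model, patterns=("110",))
        bi_all = bisite_activity_fraction(
            atp_grid, model, patterns=("110", "101", "011")
        )
        for s, f111, f110, fbi in zip(atp_grid, tri, bi, bi_all):
            rows.append(
                {
                    "kd_set": name,
                    "atp_conc_uM": float(s),
                    "f_trisite": float(f111),
                    "f_bisite_110": float(f110),
                    "f_bisite_all": float(fbi),
                }
            )
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return a JSON-serializable report.

    Stages: load or simulate observations -> fit (or echo) the apparent
    rate constant -> per-observation site-count selection and transition
    detection (when distributions are present) -> Michaelis-Menten fit
    (or echoed constants) and occupancy curves.  Identical config and
    seed give an identical report; run metadata lives in a separate
    ``provenance`` block.
    """
    report: dict[str, Any] = {"provenance": {"oxex_version": __version__,
                                             "seed": config.seed}}
    ground_truth = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        dataset = simulate_dataset(sim)
        observations = dataset.observations
        ground_truth = [
            {"atp_conc_uM": r.observation.atp_conc, "n_true": r.n_true,
             "kt_total": r.kt_total}
            for r in dataset.records
        ]
        initial = config.initial or sim.initial
    else:
        observations = read_observations(
            config.observations_path, convention=config.convention
        )
        initial = config.initial
    if not observations:
        raise DataValidationError("no observations to analyze")

    if config.k is not None:
        k = config.k
        report["rate_constant"] = {"k": k, "fitted": False}
    else:
        if config.simulation is not None:
            # dynamic-range limit set by the simulated molecule count
            n_mol = config.simulation.molecules_per_condition
            max_extent = 1.0 - 10.0 / (4.0 * n_mol)
        else:
            max_extent = 1.0 - 1e-12
        fit = fit_rate_constant(observations, max_extent=max_extent)
        k = fit.estimates["k"]
        report["rate_constant"] = {
            "k": k,
            "fitted": True,
            "se": fit.standard_errors["k"],
            "r_squared": fit.r_squared,
        }

    with_dist = [o for o in observations if o.distribution is not None]
    if with_dist and initial is not None:
        selections = [
            select_site_count(o, k, initial, config.candidates)
            for o in with_dist
        ]
        report["site_counts"] = [
            {"atp_conc_uM": o.atp_conc, "n": sel.n, "tie": sel.tie,
             "sse": {str(n): s for n, s in sel.sse.items()}}
            for o, sel in zip(with_dist, selections)
        ]
        trans = detect_transition(with_dist, k, initial,
                                  candidates=config.candidates or (2, 3))
        report["transition"] = {
            "found": trans.found,
            "time_s": trans.transition_time,
            "bracket_times_s": trans.bracket_times,
            "bracket_atp_uM": trans.bracket_atp,
            "labels": list(trans.labels),
        }

    concs = [o.atp_conc for o in observations if o.atp_conc is not None]
    if config.vmax is not None:
        vmax, km = config.vmax, config.km
        report["michaelis_menten"] = {"vmax": vmax, "km": km, "fitted": False}
    elif len(concs) >= 3 and len(concs) == len(observations):
        mm = fit_michaelis_menten(concs, [o.velocity for o in observations])
        vmax, km = mm.estimates["vmax"], mm.estimates["km"]
        report["michaelis_menten"] = {
            "vmax": vmax,
            "km": km,
            "fitted": True,
            "se": mm.standard_errors,
            "r_squared": mm.r_squared,
        }
    else:
        vmax = None

    if vmax is not None:
        report["normalized_activity"] = [
            {"atp_conc_uM": o.atp_conc,
             "v_over_vmax": float(normalized_activity([o.velocity], vmax)[0])}
            for o in observations
        ]
    if config.kd_sets and concs:
        grid = np.sort(np.unique(concs))
        report["occupancy"] = _occupancy_table(config.kd_sets, grid)
    if ground_truth is not None:
        report["ground_truth"] = ground_truth
    return report
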