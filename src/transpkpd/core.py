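"""Shared domain types, unit conventions, built-in parameter tables and I/O.

Package-wide unit conventions
-----------------------------
time                h
concentration       ng/mL (plasma), effect-compartment concentration also ng/mL
dose                mg/kg (animal studies) or absolute mg with a body weight in kg
clearance           L/h/kg
volume              L/kg
biomarker           µg Met-EF1α per mg total tumor protein

A dose of D mg/kg distributed over V/F L/kg gives mg/L; the factor 1000
to ng/mL is applied inside model code, never by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "ConvergenceError",
    "SpeciesRecord",
    "DoseRegimen",
    "ConcProfile",
    "PDObservation",
    "PKParams",
    "PDParams",
    "builtin_tables",
    "species_table",
    "read_observations",
    "write_observations",
    "HUMAN_BODY_WEIGHT_KG",
    "MOLAR_MASS_G_MOL",
]

logger = logging.getLogger("transpkpd")

#: Default human body weight (kg) used by all human-scale projections.
HUMAN_BODY_WEIGHT_KG = 70.0

#: Compound molar mass (g/mol), fixed by the printed 340 ng/mL <-> 0.88 µM
#: total-concentration equivalence.
MOLAR_MASS_G_MOL = 340.0 / 0.88


class ValidationError(ValueError):
    """An input violates a domain invariant (positivity, ordering, range)."""


class FormatError(ValidationError):
    """A file does not have the expected layout (e.g. missing column)."""


class ConvergenceError(RuntimeError):
    """An iterative procedure (optimizer, ODE solver) failed to converge."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

Species = Literal["mouse", "rat", "monkey", "dog", "human"]


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' body weight, binding, partitioning and in vivo PK.

    ``fu_plasma`` is the median unbound fraction at 5 µM; ``clint_hep`` /
    ``clint_mic`` are unbound intrinsic clearances (µL/min per 10^6 cells /
    per mg microsomal protein). In vivo fields (``cl_obs`` L/h/kg,
    ``vss_obs`` L/kg, ``f_obs`` fraction) are absent (None) for human.
    """

    species: str
    body_weight: float
    fu_plasma: float
    bp_ratio: float
    clint_hep: float
    clint_mic: float
    cl_obs: float | None = None
    vss_obs: float | None = None
    f_obs: float | None = None

    def __post_init__(self) -> None:
        _require(self.body_weight > 0, f"{self.species}: body_weight must be > 0")
        _require(0 < self.fu_plasma <= 1, f"{self.species}: fu_plasma must be in (0, 1]")
        _require(self.bp_ratio > 0, f"{self.species}: bp_ratio must be > 0")
        _require(self.clint_hep >= 0, f"{self.species}: clint_hep must be >= 0")
        _require(self.clint_mic >= 0, f"{self.species}: clint_mic must be >= 0")
        for name in ("cl_obs", "vss_obs", "f_obs"):
            v = getattr(self, name)
            if v is not None:
                _require(v > 0, f"{self.species}: {name} must be > 0 when present")


@dataclass(frozen=True)
class DoseRegimen:
    """An oral or i.v. multiple-dose regimen with a fixed dosing interval.

    ``dose`` is mg/kg for animal studies or absolute mg when paired with a
    subject body weight downstream.
    """

    dose: float
    interval: float = 24.0
    n_doses: int = 1
    route: Literal["oral", "iv"] = "oral"

    def __post_init__(self) -> None:
        _require(self.dose > 0, "dose must be > 0")
        _require(self.n_doses >= 1, "n_doses must be >= 1")
        if self.n_doses > 1:
            _require(self.interval > 0, "interval must be > 0 for n_doses > 1")
        _require(self.route in ("oral", "iv"), f"unknown route {self.route!r}")

    @property
    def dose_times(self) -> np.ndarray:
        """Administration times (h since first dose)."""
        return np.arange(self.n_doses) * self.interval

    @property
    def duration(self) -> float:
        """Time of the last administration (h since first dose)."""
        return (self.n_doses - 1) * self.interval


@dataclass
class ConcProfile:
    """A plasma concentration-time profile for one subject (or pooled id)."""

    subject_id: str
    regimen: DoseRegimen
    times: np.ndarray
    concs: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        _require(self.times.shape == self.concs.shape, "times and concs must have equal length")
        _require(self.times.size >= 1, "profile must contain at least one sample")
        _require(np.all(np.diff(self.times) > 0), "times must be strictly increasing")
        _require(np.all(self.times >= 0), "times must be >= 0")
        _require(np.all(self.concs >= 0), "concentrations must be >= 0")


@dataclass(frozen=True)
class PDObservation:
    """A single tumor Met-EF1α measurement (destructive sampling)."""

    subject_id: str
    regimen: DoseRegimen
    time: float
    met_ef1a: float

    def __post_init__(self) -> None:
        _require(self.time >= 0, "time must be >= 0")
        _require(self.met_ef1a >= 0, "met_ef1a must be >= 0")


@dataclass(frozen=True)
class PKParams:
    """One-compartment oral PK parameters: ka (1/h), CL/F (L/h/kg), V/F (L/kg)."""

    ka: float
    cl_f: float
    v_f: float

    def __post_init__(self) -> None:
        _require(self.ka > 0, "ka must be > 0")
        _require(self.cl_f > 0, "cl_f must be > 0")
        _require(self.v_f > 0, "v_f must be > 0")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V (1/h)."""
        return self.cl_f / self.v_f

    @property
    def t_half(self) -> float:
        """Elimination half-life ln(2)/ke (h)."""
        return np.log(2.0) / self.ke


@dataclass(frozen=True)
class PDParams:
    """Effect-compartment + turnover PD parameters.

    ke0 (1/h) first-order equilibration into the effect compartment; kin
    (µg/mg/h) zero-order biomarker synthesis; kout (1/h) first-order
    degradation, inhibited by drug with maximal extent imax and potency
    ic50 (ng/mL, effect-compartment scale).
    """

    ke0: float
    kin: float
    kout: float
    imax: float
    ic50: float

    def __post_init__(self) -> None:
        for name in ("ke0", "kin", "kout", "ic50"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(0 <= self.imax <= 1, "imax must be in [0, 1]")

    @property
    def baseline(self) -> float:
        """Pre-dose biomarker level kin/kout (µg/mg)."""
        return self.kin / self.kout

    @property
    def e_max_asymptote(self) -> float:
        """Upper bound of the biomarker under full inhibition, kin/(kout·(1−imax))."""
        if self.imax >= 1.0:
            return np.inf
        return self.kin / (self.kout * (1.0 - self.imax))


# ---------------------------------------------------------------------------
# Built-in study tables
# ---------------------------------------------------------------------------

# Species in vitro parameters (unbound CLint in hepatocytes µL/min/10^6 cells
# and liver microsomes µL/min/mg protein; median fu at 5 µM; B/P ratio) and
# in vivo PK means from the single-dose i.v./p.o. studies (body weight kg,
# plasma CL L/h/kg, Vss L/kg, oral F). Human has no in vivo record.
_SPECIES_ROWS: tuple[SpeciesRecord, ...] = (
    SpeciesRecord("mouse", 0.029, 0.032, 0.71, 120.0, 60.0, cl_obs=0.378, vss_obs=0.37, f_obs=0.38),
    SpeciesRecord("rat", 0.270, 0.096, 0.74, 30.0, 29.0, cl_obs=0.350, vss_obs=1.30, f_obs=0.72),
    SpeciesRecord("monkey", 4.60, 0.044, 0.73, 3.8, 19.0, cl_obs=0.078, vss_obs=0.41, f_obs=0.68),
    SpeciesRecord("dog", 8.36, 0.019, 0.59, 3.6, 11.0, cl_obs=0.034, vss_obs=0.23, f_obs=0.80),
    SpeciesRecord("human", HUMAN_BODY_WEIGHT_KG, 0.018, 0.58, 6.0, 12.0),
)

#: Mouse xenograft PK estimates (naive pooled fit; ka was fixed).
MOUSE_PK = PKParams(ka=2.7, cl_f=0.415, v_f=1.034)

#: Mouse xenograft PD estimates.
MOUSE_PD = PDParams(ke0=0.0566, kin=29.1, kout=1.45, imax=0.91, ic50=340.0)


def builtin_tables() -> tuple[list[SpeciesRecord], PKParams, PDParams]:
    """Return the built-in species records and the mouse PK/PD estimates.

    The species list covers mouse, rat, monkey, dog and human (the human
    record carries in vitro data only).
    """
    return list(_SPECIES_ROWS), MOUSE_PK, MOUSE_PD


def species_table(species: str | None = None) -> SpeciesRecord | list[SpeciesRecord]:
    """Look up one species record by name, or all records if ``species`` is None."""
    if species is None:
        return list(_SPECIES_ROWS)
    for rec in _SPECIES_ROWS:
        if rec.species == species:
            return rec
    raise ValidationError(f"unknown species {species!r}")


# ---------------------------------------------------------------------------
# Observation I/O (long-format CSV)
# ---------------------------------------------------------------------------

_OBS_COLUMNS = ["subject", "time_h", "value", "dose_mg_kg", "interval_h", "n_doses", "route"]


def _regimen_from_row(row: pd.Series) -> DoseRegimen:
    return DoseRegimen(
        dose=float(row["dose_mg_kg"]),
        interval=float(row["interval_h"]),
        n_doses=int(row["n_doses"]),
        route=str(row["route"]),
    )


def read_observations(
    path: str | Path, kind: Literal["conc", "pd"]
) -> list[ConcProfile] | list[PDObservation]:
    """Read a long-format observation CSV.

    Expected header: ``subject, time_h, value, dose_mg_kg, interval_h,
    n_doses, route``. For ``kind="conc"`` rows are grouped per subject into
    :class:`ConcProfile` objects (out-of-order times are re-sorted with a
    warning); for ``kind="pd"`` each row becomes a :class:`PDObservation`.
    Row / subject-first-appearance order is preserved.
    """
    if kind not in ("conc", "pd"):
        raise ValidationError(f"kind must be 'conc' or 'pd', got {kind!r}")
    df = pd.read_csv(path)
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    for i, row in df.iterrows():
        if row["time_h"] < 0:
            raise ValidationError(f"{path}: negative time_h in row {i + 1}")
        if row["value"] < 0:
            raise ValidationError(f"{path}: negative value in row {i + 1}")

    if kind == "pd":
        return [
            PDObservation(
                subject_id=str(row["subject"]),
                regimen=_regimen_from_row(row),
                time=float(row["time_h"]),
                met_ef1a=float(row["value"]),
            )
            for _, row in df.iterrows()
        ]

    profiles: list[ConcProfile] = []
    for subject, grp in df.groupby("subject", sort=False):
        times = grp["time_h"].to_numpy(dtype=float)
        if not np.all(np.diff(times) > 0):
            logger.warning("subject %s: times out of order, re-sorting", subject)
            grp = grp.sort_values("time_h")
            times = grp["time_h"].to_numpy(dtype=float)
        profiles.append(
            ConcProfile(
                subject_id=str(subject),
                regimen=_regimen_from_row(grp.iloc[0]),
                times=times,
                concs=grp["value"].to_numpy(dtype=float),
            )
        )
    return profiles


def write_observations(
    path: str | Path,
    records: Sequence[ConcProfile] | Sequence[PDObservation],
) -> None:
    """Write observations to the long-format CSV read by :func:`read_observations`.

    Values are written with full precision (repr round-trip).
    """
    rows: list[dict] = []
    for rec in records:
        if isinstance(rec, ConcProfile):
            for t, c in zip(rec.times, rec.concs):
                rows.append(_obs_row(rec.subject_id, rec.regimen, t, c))
        elif isinstance(rec, PDObservation):
            rows.append(_obs_row(rec.subject_id, rec.regimen, rec.time, rec.met_ef1a))
        else:
            raise ValidationError(f"cannot serialize record of type {type(rec).__name__}")
    pd.DataFrame(rows, columns=_OBS_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def _obs_row(subject: str, regimen: DoseRegimen, time: float, value: float) -> dict:
    return {
        "subject": subject,
        "time_h": time,
        "value": value,
        "dose_mg_kg": regimen.dose,
        "interval_h": regimen.interval,
        "n_doses": regimen.n_doses,
        "route": regimen.route,
    }
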