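"""Synthetic mouse xenograft PK/PD study generation.

Emulates destructive-sampling designs: at each scheduled time point a group
of animals is sacrificed and each contributes one plasma concentration and
one tumor Met-EF1α level. Observations are the model predictions under the
true parameters perturbed by multiplicative lognormal noise with median 1
and a configurable coefficient of variation (default 20%, a typical
preclinical assay spread).

Built-in designs:

* ``PKPD-01`` — single oral dose of 10/25/100 mg/kg, sampling 1, 7, 24, 48,
  72, 96 h post dose, n = 5 per time point.
* ``PKPD-02`` — four daily oral doses at the same dose levels, same sampling
  clock (h since first dose).
* ``EFF-01``  — six weeks of daily dosing; sampling 1, 7, 24 h after the
  last (42nd) dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConcProfile, DoseRegimen, PDObservation, PDParams, PKParams, ValidationError
from .model import simulate_pkpd

__all__ = ["StudyDesign", "SyntheticStudy", "study_design", "generate_study", "DEFAULT_NOISE_CV"]

#: Default observation CV (fractional) for both assays.
DEFAULT_NOISE_CV = 0.2

_DOSE_LEVELS = (10.0, 25.0, 100.0)


@dataclass(frozen=True)
class StudyDesign:
    """A destructive-sampling study layout."""

    name: str
    regimens: tuple[DoseRegimen, ...]
    sample_times: tuple[float, ...]
    n_per_timepoint: int = 5
    destructive: bool = True

    def __post_init__(self) -> None:
        if self.n_per_timepoint < 1:
            raise ValidationError("n_per_timepoint must be >= 1")
        if not self.regimens:
            raise ValidationError("design needs at least one regimen")
        if not self.sample_times or any(t < 0 for t in self.sample_times):
            raise ValidationError("sample_times must be non-empty and >= 0")


def study_design(name: str, n_per_timepoint: int = 5) -> StudyDesign:
    """Construct one of the built-in designs by name."""
    key = name.upper().replace("_", "-")
    if key == "PKPD-01":
        regimens = tuple(DoseRegimen(d, interval=24.0, n_doses=1) for d in _DOSE_LEVELS)
        times = (1.0, 7.0, 24.0, 48.0, 72.0, 96.0)
    elif key == "PKPD-02":
        regimens = tuple(DoseRegimen(d, interval=24.0, n_doses=4) for d in _DOSE_LEVELS)
        times = (1.0, 7.0, 24.0, 48.0, 72.0, 96.0)
    elif key == "EFF-01":
        regimens = tuple(DoseRegimen(d, interval=24.0, n_doses=42) for d in _DOSE_LEVELS)
        last = 41 * 24.0
        times = (last + 1.0, last + 7.0, last + 24.0)
    else:
        raise ValidationError(f"unknown study design {name!r}")
    return StudyDesign(name=key, regimens=regimens, sample_times=times, n_per_timepoint=n_per_timepoint)


@dataclass
class SyntheticStudy:
    """A generated dataset plus the truth that produced it."""

    design: StudyDesign
    true_pk: PKParams
    true_pd: PDParams
    noise_cv: float
    seed: int
    conc_obs: list[ConcProfile] = field(default_factory=list)
    pd_obs: list[PDObservation] = field(default_factory=list)


def generate_study(
    design: StudyDesign,
    true_pk: PKParams,
    true_pd: PDParams,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate one study: model predictions times lognormal noise.

    The lognormal is parameterized so its median is 1 and its natural-scale
    CV equals ``noise_cv`` (sigma² = ln(1 + cv²)). Concentration and
    biomarker noises are drawn independently. Regeneration with the same
    seed is bit-identical.
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    times = np.asarray(sorted(design.sample_times), dtype=float)
    study = SyntheticStudy(design, true_pk, true_pd, noise_cv, seed)
    for regimen in design.regimens:
        grid = np.unique(np.concatenate(([0.0], times)))
        sim = simulate_pkpd(regimen, true_pk, true_pd, grid=grid)
        idx = np.searchsorted(grid, times)
        c_pred, e_pred = sim.conc[idx], sim.effect[idx]
        for t, c, e in zip(times, c_pred, e_pred):
            for animal in range(design.n_per_timepoint):
                sid = f"{design.name}-d{regimen.dose:g}-t{t:g}-a{animal + 1}"
                c_obs = c * float(np.exp(rng.normal(0.0, sigma))) if noise_cv > 0 else c
                e_obs = e * float(np.exp(rng.normal(0.0, sigma))) if noise_cv > 0 else e
                study.conc_obs.append(
                    ConcProfile(subject_id=sid, regimen=regimen, times=np.array([t]), concs=np.array([c_obs]))
                )
                study.pd_obs.append(
                    PDObservation(subject_id=sid, regimen=regimen, time=float(t), met_ef1a=float(e_obs))
                )
    return study
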