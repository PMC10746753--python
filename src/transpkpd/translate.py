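"""Human dose projection.

The mouse xenograft PK/PD model is carried to humans unchanged on the PD
side (the biomarker turnover is assumed conserved, the tumors being human
xenografts), while the PK side is replaced by the predicted human
one-compartment parameters. The PD target is the steady-state biomarker
minimum maintained by the minimal efficacious mouse regimen, rounded down
to a configurable granularity; the human dose is the smallest dose on a
5 mg grid whose steady-state biomarker minimum reaches that target, and the
associated steady-state trough concentration is reported.

The absorption inputs (F, ka) of the human simulation are explicit
configuration with a sensitivity scan, because they come from an absorption
model that is not part of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    HUMAN_BODY_WEIGHT_KG,
    ConvergenceError,
    DoseRegimen,
    MOUSE_PD,
    PDParams,
    PKParams,
    ValidationError,
)
from .model import steady_state_metrics

__all__ = [
    "TranslationConfig",
    "derive_pd_target",
    "find_human_dose",
    "ctrough_closed_form",
    "sensitivity_scan",
    "PD_TARGET_GRANULARITY",
]

#: Default rounding granularity (µg/mg) when turning a simulated biomarker
#: minimum into a round target level.
PD_TARGET_GRANULARITY = 25.0

#: Dose search grid (mg).
DOSE_GRID_MG = 5.0

#: Upper bound of the dose search (mg); beyond this the target is treated
#: as unreachable in practice.
_MAX_DOSE_MG = 100000.0


@dataclass(frozen=True)
class TranslationConfig:
    """Inputs of the human projection.

    ``human_cl``/``human_vss`` are the predicted i.v. disposition parameters
    (L/h/kg, L/kg); ``f_oral`` and ``ka`` describe absorption; PD parameters
    are assumed conserved from mouse. ``target_e_min`` is the biomarker
    level (µg/mg) the steady-state minimum must reach.
    """

    human_cl: float = 0.020
    human_vss: float = 0.21
    f_oral: float = 0.6
    ka: float = 0.35
    body_weight: float = HUMAN_BODY_WEIGHT_KG
    pd_params: PDParams = field(default_factory=lambda: MOUSE_PD)
    target_e_min: float = 125.0

    def __post_init__(self) -> None:
        for name in ("human_cl", "human_vss", "f_oral", "ka", "body_weight", "target_e_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.f_oral > 1:
            raise ValidationError("f_oral must be in (0, 1]")

    @property
    def pk_params(self) -> PKParams:
        """Apparent oral PK parameters CL/F and V/F."""
        return PKParams(ka=self.ka, cl_f=self.human_cl / self.f_oral, v_f=self.human_vss / self.f_oral)

    @classmethod
    def from_dict(cls, d: dict) -> "TranslationConfig":
        d = dict(d)
        if "pd_params" in d and isinstance(d["pd_params"], dict):
            d["pd_params"] = PDParams(**d["pd_params"])
        return cls(**d)


def derive_pd_target(
    pk: PKParams,
    pd_params: PDParams,
    efficacious_regimen: DoseRegimen,
    granularity: float = PD_TARGET_GRANULARITY,
) -> float:
    """PD target from the minimal efficacious regimen.

    Simulates the regimen to steady state and rounds the biomarker minimum
    down to the nearest multiple of ``granularity`` (a round threshold the
    trajectory is maintained above).
    """
    if granularity <= 0:
        raise ValidationError("granularity must be > 0")
    ss = steady_state_metrics(efficacious_regimen, pk, pd_params)
    if not ss.converged:
        raise ConvergenceError("steady state not reached for the efficacious regimen")
    return float(np.floor(ss.e_min / granularity) * granularity)


def _human_ss(config: TranslationConfig, dose_mg: float, interval: float):
    regimen = DoseRegimen(dose=dose_mg / config.body_weight, interval=interval, n_doses=100000)
    return steady_state_metrics(regimen, config.pk_params, config.pd_params)


def find_human_dose(
    config: TranslationConfig,
    interval: float = 24.0,
    dose_grid: float = DOSE_GRID_MG,
) -> tuple[float, float, float]:
    """Smallest grid dose whose steady-state biomarker minimum meets the target.

    Returns (dose mg, steady-state C_trough ng/mL, steady-state E_min µg/mg).
    Raises a validation error when the target exceeds the asymptotic maximum
    biomarker level kin/(kout·(1−imax)).
    """
    if config.target_e_min >= config.pd_params.e_max_asymptote:
        raise ValidationError(
            f"target {config.target_e_min} µg/mg is not reachable: asymptotic "
            f"maximum is {config.pd_params.e_max_asymptote:.4g} µg/mg"
        )

    cache: dict[float, tuple[float, float]] = {}

    def e_min_at(dose: float) -> float:
        if dose not in cache:
            ss = _human_ss(config, dose, interval)
            cache[dose] = (ss.e_min, ss.c_trough)
        return cache[dose][0]

    # bracket on the grid by doubling
    lo_n, hi_n = 0, 1
    while e_min_at(hi_n * dose_grid) < config.target_e_min:
        lo_n = hi_n
        hi_n *= 2
        if hi_n * dose_grid > _MAX_DOSE_MG:
            raise ConvergenceError("dose search exceeded the practical maximum")
    # bisection on grid indices: e_min(lo) < target <= e_min(hi)
    while hi_n - lo_n > 1:
        mid = (lo_n + hi_n) // 2
        if e_min_at(mid * dose_grid) >= config.target_e_min:
            hi_n = mid
        else:
            lo_n = mid
    dose = hi_n * dose_grid
    e_min, c_trough = cache[dose]
    return dose, c_trough, e_min


def ctrough_closed_form(dose_mg: float, config: TranslationConfig, interval: float) -> float:
    """Steady-state trough concentration (ng/mL) of the oral one-compartment model.

    F·D/V · ka/(ka−ke) · [q_e/(1−q_e) − q_a/(1−q_a)] with q_e = exp(−ke·τ),
    q_a = exp(−ka·τ); the ka = ke limit uses F·D/V·ke·τ·q/(1−q)².
    """
    if dose_mg <= 0 or interval <= 0:
        raise ValidationError("dose and interval must be > 0")
    pk = config.pk_params
    ka, ke = pk.ka, pk.ke
    # F·D/V in ng/mL: dose/(V/F · BW) mg/L × 1000
    fdv = dose_mg / (pk.v_f * config.body_weight) * 1000.0
    tau = interval
    if abs(ka - ke) < 1.0e-9 * ka:
        q = np.exp(-ke * tau)
        return float(fdv * ke * tau * q / (1.0 - q) ** 2)
    qe, qa = np.exp(-ke * tau), np.exp(-ka * tau)
    return float(fdv * ka / (ka - ke) * (qe / (1.0 - qe) - qa / (1.0 - qa)))


def sensitivity_scan(
    config: TranslationConfig,
    f_values=(0.6, 0.7, 0.8),
    bw_values=(60.0, 70.0),
    interval: float = 24.0,
    reference_dose_mg: float | None = None,
) -> pd.DataFrame:
    """Required dose and trough across absorption/body-weight assumptions.

    One row per (F, body weight) combination: the smallest dose meeting the
    PD target, its steady-state trough and biomarker minimum, and — when
    ``reference_dose_mg`` is given — the closed-form steady-state trough at
    that reference dose under the same assumptions.
    """
    rows = []
    for f in f_values:
        for bw in bw_values:
            cfg = replace(config, f_oral=f, body_weight=bw)
            dose, c_trough, e_min = find_human_dose(cfg, interval=interval)
            row = {
                "f_oral": f,
                "body_weight_kg": bw,
                "dose_mg": dose,
                "c_trough_ng_ml": c_trough,
                "e_min_ug_mg": e_min,
            }
            if reference_dose_mg is not None:
                row["c_trough_at_reference_ng_ml"] = ctrough_closed_form(reference_dose_mg, cfg, interval)
            rows.append(row)
    return pd.DataFrame(rows)
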