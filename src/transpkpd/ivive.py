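"""In vitro–in vivo extrapolation of hepatic clearance.

Unbound intrinsic clearance measured in hepatocytes or liver microsomes is
scaled to a whole-body in vivo CLint with physiological scaling factors
(cells or mg microsomal protein per g liver, g liver per kg body weight) and
converted to hepatic plasma clearance with a liver blood-flow model that
incorporates plasma protein binding and the blood-to-plasma ratio:

    CL_H = Qh · fu · CLint / (Qh + fu · CLint / (B/P))

This algebra is the well-stirred form; a true parallel-tube alternative
(CL_blood = Qh·(1 − exp(−fu·CLint/(Qh·B/P))), converted back to plasma
clearance) is available behind the ``model="parallel-tube"`` flag for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError

__all__ = [
    "PhysioConstants",
    "DEFAULT_PHYSIO",
    "microsomal_fu_inc",
    "scale_clint",
    "hepatic_cl_eq1",
    "hepatic_cl",
    "extraction_ratio",
    "predict_cl_all_species",
]


@dataclass(frozen=True)
class PhysioConstants:
    """Physiological scaling constants for one species.

    hepatocellularity  10^6 cells per g liver
    microsomal_protein mg microsomal protein per g liver
    liver_weight       g liver per kg body weight
    q_h                hepatic blood flow, L/h/kg
    """

    species: str
    hepatocellularity: float
    microsomal_protein: float
    liver_weight: float
    q_h: float

    def __post_init__(self) -> None:
        for name in ("hepatocellularity", "microsomal_protein", "liver_weight", "q_h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{self.species}: {name} must be > 0")


# Literature physiology. Human values anchored to hepatocellularity
# 99e6 cells/g, liver 24.4 g/kg and Qh 1.16 L/h/kg; animal values sit within
# published ranges and reproduce the observed cross-species IVIVE concordance
# (predictions within ~0.5–3-fold of observed plasma clearances).
DEFAULT_PHYSIO: dict[str, PhysioConstants] = {
    "mouse": PhysioConstants("mouse", 110.0, 45.0, 55.0, 5.40),
    "rat": PhysioConstants("rat", 117.0, 44.8, 36.6, 3.31),
    "monkey": PhysioConstants("monkey", 120.0, 45.0, 34.0, 2.62),
    "dog": PhysioConstants("dog", 215.0, 55.4, 32.9, 1.85),
    "human": PhysioConstants("human", 99.0, 40.0, 24.4, 1.16),
}


def microsomal_fu_inc(logd: float, protein_conc: float) -> float:
    """Unbound fraction in a microsomal incubation (Hallifax–Houston form).

    fu_inc = 1 / (1 + P · 10^(0.072·logD² + 0.067·logD − 1.126)) with P the
    microsomal protein concentration in mg/mL.
    """
    if protein_conc < 0:
        raise ValidationError("protein_conc must be >= 0")
    return 1.0 / (1.0 + protein_conc * 10.0 ** (0.072 * logd**2 + 0.067 * logd - 1.126))


def scale_clint(clu_int: float, system: str, constants: PhysioConstants) -> float:
    """Scale an unbound in vitro CLint to whole-body in vivo CLint (L/h/kg).

    ``clu_int`` is µL/min per 10^6 cells (``system="hepatocyte"``) or µL/min
    per mg microsomal protein (``system="microsome"``).
    """
    if clu_int < 0:
        raise ValidationError("clu_int must be >= 0")
    if system == "hepatocyte":
        per_g_liver = clu_int * constants.hepatocellularity
    elif system == "microsome":
        per_g_liver = clu_int * constants.microsomal_protein
    else:
        raise ValidationError(f"unknown system {system!r} (expected 'hepatocyte' or 'microsome')")
    per_kg_bw = per_g_liver * constants.liver_weight  # µL/min/kg
    return per_kg_bw * 1.0e-6 * 60.0  # -> L/h/kg


def hepatic_cl_eq1(q_h: float, fu: float, clint: float, bp: float) -> float:
    """Hepatic plasma clearance (L/h/kg) from the flow/binding model.

    CL_H = Qh·fu·CLint / (Qh + fu·CLint/(B/P)); bounded above by Qh·(B/P).
    """
    _check_flow_inputs(q_h, fu, clint, bp)
    return q_h * fu * clint / (q_h + fu * clint / bp)


def hepatic_cl(q_h: float, fu: float, clint: float, bp: float, model: str = "well-stirred") -> float:
    """Hepatic plasma clearance with a choice of liver model.

    ``model="well-stirred"`` is :func:`hepatic_cl_eq1`; ``model="parallel-tube"``
    computes blood clearance Qh·(1 − exp(−fu·CLint/(Qh·B/P))) and converts to
    plasma clearance by multiplying with B/P.
    """
    if model == "well-stirred":
        return hepatic_cl_eq1(q_h, fu, clint, bp)
    if model == "parallel-tube":
        _check_flow_inputs(q_h, fu, clint, bp)
        cl_blood = q_h * -np.expm1(-fu * clint / (q_h * bp))
        return float(cl_blood * bp)
    raise ValidationError(f"unknown liver model {model!r}")


def _check_flow_inputs(q_h: float, fu: float, clint: float, bp: float) -> None:
    if q_h <= 0:
        raise ValidationError("q_h must be > 0")
    if not 0 < fu <= 1:
        raise ValidationError("fu must be in (0, 1]")
    if clint < 0:
        raise ValidationError("clint must be >= 0")
    if bp <= 0:
        raise ValidationError("bp must be > 0")


def extraction_ratio(cl_plasma: float, q_h: float) -> float:
    """Hepatic first-pass extraction, percent of liver blood flow: 100·CL/Qh."""
    if q_h <= 0:
        raise ValidationError("q_h must be > 0")
    if cl_plasma < 0:
        raise ValidationError("cl_plasma must be >= 0")
    return 100.0 * cl_plasma / q_h


def predict_cl_all_species(
    records,
    system: str = "hepatocyte",
    physio: dict[str, PhysioConstants] | None = None,
    model: str = "well-stirred",
) -> dict[str, float]:
    """IVIVE-predicted hepatic plasma clearance (L/h/kg) per species record."""
    physio = physio or DEFAULT_PHYSIO
    out: dict[str, float] = {}
    for rec in records:
        consts = physio[rec.species]
        clu = rec.clint_hep if system == "hepatocyte" else rec.clint_mic
        clint = scale_clint(clu, system, consts)
        out[rec.species] = hepatic_cl(consts.q_h, rec.fu_plasma, clint, rec.bp_ratio, model=model)
    return out
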