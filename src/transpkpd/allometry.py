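"""Human CL and Vss prediction by interspecies scaling.

All regressions are ordinary least squares of log10(absolute quantity) on
log10(body weight) over the animal species means. Methods implemented:

* ``NAS_fub`` — allometry of clearance normalized by plasma fu and corrected
  by the human/species ratio of microsomal unbound CLint, back-multiplied by
  human fu.
* ``SA_fub`` — allometry of Vss normalized by plasma fu, back-multiplied by
  human fu.
* ``SA/RoE`` — simple allometry of clearance, with the rule of exponents
  selecting plain allometry (exponent < 0.71), the maximum-lifespan-potential
  product (0.71–1.0) or the brain-weight product (> 1.0).
* Tang–Mayersohn clearance from the simple-allometry coefficient and the
  rat/human fu ratio.
* Øie–Tozer Vss via a solved apparent tissue unbound fraction, and the
  human–dog fu-proportionality model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import HUMAN_BODY_WEIGHT_KG, SpeciesRecord, ValidationError

__all__ = [
    "AllometryFit",
    "HumanPrediction",
    "fit_loglog",
    "nas_fub_cl",
    "sa_fub_vss",
    "simple_allometry_cl",
    "rule_of_exponents_cl",
    "tang_mayersohn_cl",
    "tang_mayersohn_from_records",
    "oie_tozer_vss",
    "dog_proportionality_vss",
    "halflife",
    "combine_predictions",
    "predict_all",
    "MLP_YEARS",
    "BRAIN_WEIGHT_KG",
    "OIE_TOZER_VOLUMES",
    "RE_I_RATIO",
]

logger = logging.getLogger("transpkpd")

#: Maximum lifespan potential (years) used by the rule-of-exponents product
#: method. Standard comparative-physiology values.
MLP_YEARS: dict[str, float] = {
    "mouse": 2.7,
    "rat": 4.7,
    "monkey": 22.3,
    "dog": 19.7,
    "human": 93.4,
}

#: Brain weight (kg) for the brain-weight product method.
BRAIN_WEIGHT_KG: dict[str, float] = {
    "mouse": 0.0004,
    "rat": 0.002,
    "monkey": 0.07,
    "dog": 0.08,
    "human": 1.53,
}

#: Øie–Tozer physiological volumes (L/kg): plasma Vp, extracellular fluid Ve,
#: remainder ("tissue") Vr. Standard literature set.
OIE_TOZER_VOLUMES: dict[str, tuple[float, float, float]] = {
    "mouse": (0.0500, 0.265, 0.364),
    "rat": (0.0313, 0.265, 0.364),
    "monkey": (0.0448, 0.208, 0.485),
    "dog": (0.0515, 0.216, 0.450),
    "human": (0.0436, 0.151, 0.380),
}

#: Ratio of binding proteins in extracellular fluid to plasma (RE/I).
RE_I_RATIO = 1.4


@dataclass(frozen=True)
class AllometryFit:
    """Log-log power-law fit y = coefficient · BW^exponent.

    ``coefficient`` is the fitted value at 1 kg body weight in the units of
    the regressed quantity; ``correction`` records which normalization was
    applied to the inputs before fitting.
    """

    coefficient: float
    exponent: float
    r_squared: float
    correction: str = "none"

    def predict(self, body_weight: float) -> float:
        """Predicted absolute quantity at ``body_weight`` kg."""
        return self.coefficient * body_weight**self.exponent


@dataclass(frozen=True)
class HumanPrediction:
    """A human PK parameter estimate from one scaling method (or their mean)."""

    method: str
    cl: float | None = None
    vss: float | None = None
    t_half: float | None = None
    cl_sd: float | None = None
    vss_sd: float | None = None
    fit: AllometryFit | None = None
    branch: str | None = None

    def __post_init__(self) -> None:
        if self.cl is None and self.vss is None:
            raise ValidationError(f"{self.method}: at least one of cl/vss must be present")
        for name in ("cl", "vss", "t_half"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{self.method}: {name} must be > 0")


def fit_loglog(body_weights, values, correction: str = "none") -> AllometryFit:
    """OLS of log10(value) on log10(body weight).

    Requires at least two species and strictly positive inputs. R² is the
    coefficient of determination of the log-scale regression.
    """
    bw = np.asarray(body_weights, dtype=float)
    y = np.asarray(values, dtype=float)
    if bw.size != y.size:
        raise ValidationError("body_weights and values must have equal length")
    if bw.size < 2:
        raise ValidationError("allometric fit requires at least 2 species")
    if np.any(bw <= 0) or np.any(y <= 0):
        raise ValidationError("allometric inputs must be > 0")
    x, ly = np.log10(bw), np.log10(y)
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValidationError("body weights must not all be equal")
    slope = float(np.sum((x - x.mean()) * (ly - ly.mean())) / sxx)
    intercept = float(ly.mean() - slope * x.mean())
    resid = ly - (intercept + slope * x)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return AllometryFit(coefficient=10.0**intercept, exponent=slope, r_squared=r2, correction=correction)


def _animal_records(records) -> list[SpeciesRecord]:
    recs = [r for r in records if r.species != "human"]
    if len(recs) < 2:
        raise ValidationError("need at least 2 animal species records")
    return recs


def _need(rec: SpeciesRecord, field: str) -> float:
    v = getattr(rec, field)
    if v is None:
        raise ValidationError(f"species {rec.species!r}: missing required field {field!r}")
    return v


def nas_fub_cl(
    records, human: SpeciesRecord, human_bw: float = HUMAN_BODY_WEIGHT_KG
) -> HumanPrediction:
    """Human clearance by fu-normalized, microsomal-CLint-corrected allometry.

    Per animal: (CL_obs/fu) · (CLint_mic,human/CLint_mic,species) · BW gives
    a corrected absolute clearance (L/h); these are regressed log-log against
    body weight, evaluated at ``human_bw``, back-multiplied by human fu and
    expressed per kg.
    """
    recs = _animal_records(records)
    bw = np.array([r.body_weight for r in recs])
    y = np.array(
        [
            (_need(r, "cl_obs") / r.fu_plasma) * (human.clint_mic / _need(r, "clint_mic")) * r.body_weight
            for r in recs
        ]
    )
    fit = fit_loglog(bw, y, correction="fu_and_clint")
    cl = fit.predict(human_bw) * human.fu_plasma / human_bw
    return HumanPrediction(method="NAS_fub", cl=cl, fit=fit)


def sa_fub_vss(
    records, human: SpeciesRecord, human_bw: float = HUMAN_BODY_WEIGHT_KG
) -> HumanPrediction:
    """Human Vss by allometry of fu-normalized absolute volumes."""
    recs = _animal_records(records)
    bw = np.array([r.body_weight for r in recs])
    y = np.array([(_need(r, "vss_obs") / r.fu_plasma) * r.body_weight for r in recs])
    fit = fit_loglog(bw, y, correction="fu")
    vss = fit.predict(human_bw) * human.fu_plasma / human_bw
    return HumanPrediction(method="SA_fub", vss=vss, fit=fit)


def simple_allometry_cl(records) -> AllometryFit:
    """Simple allometry of absolute clearance (L/h) vs body weight."""
    recs = _animal_records(records)
    bw = np.array([r.body_weight for r in recs])
    y = np.array([_need(r, "cl_obs") * r.body_weight for r in recs])
    return fit_loglog(bw, y)


def rule_of_exponents_cl(
    records,
    human_bw: float = HUMAN_BODY_WEIGHT_KG,
    mlp_table: dict[str, float] | None = None,
    brw_table: dict[str, float] | None = None,
) -> HumanPrediction:
    """Human clearance by simple allometry with the rule-of-exponents branch.

    Exponent b < 0.71: plain simple allometry; 0.71 <= b <= 1.0: regression
    of CL·MLP with division by human MLP; b > 1.0: regression of CL·BrW with
    division by human brain weight. The branch taken is recorded on the
    result.
    """
    recs = _animal_records(records)
    sa = simple_allometry_cl(records)
    bw = np.array([r.body_weight for r in recs])
    if sa.exponent < 0.71:
        cl = sa.predict(human_bw) / human_bw
        return HumanPrediction(method="SA/RoE", cl=cl, fit=sa, branch="simple_allometry")
    if sa.exponent <= 1.0:
        table, human_const, branch = mlp_table or MLP_YEARS, None, "mlp_product"
    else:
        table, human_const, branch = brw_table or BRAIN_WEIGHT_KG, None, "brain_weight_product"
    try:
        consts = np.array([table[r.species] for r in recs])
        human_const = table["human"]
    except KeyError as exc:
        raise ValidationError(f"missing rule-of-exponents constant for species {exc}") from exc
    y = np.array([_need(r, "cl_obs") * r.body_weight for r in recs]) * consts
    fit = fit_loglog(bw, y, correction="product")
    cl = fit.predict(human_bw) / human_const / human_bw
    return HumanPrediction(method="SA/RoE", cl=cl, fit=fit, branch=branch)


def tang_mayersohn_cl(
    sa_coefficient_ml_min: float,
    fu_rat: float,
    fu_human: float,
    human_bw: float = HUMAN_BODY_WEIGHT_KG,
) -> float:
    """Tang–Mayersohn human clearance (L/h/kg).

    CL_human (mL/min) = 33.35 · (a / Rfu)^0.77 where ``a`` is the
    simple-allometry coefficient in mL/min at 1 kg and Rfu = fu_rat/fu_human.
    """
    for name, v in (
        ("sa_coefficient_ml_min", sa_coefficient_ml_min),
        ("fu_rat", fu_rat),
        ("fu_human", fu_human),
        ("human_bw", human_bw),
    ):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0")
    rfu = fu_rat / fu_human
    cl_ml_min = 33.35 * (sa_coefficient_ml_min / rfu) ** 0.77
    return cl_ml_min * 60.0 / 1000.0 / human_bw


def tang_mayersohn_from_records(
    records, human: SpeciesRecord, human_bw: float = HUMAN_BODY_WEIGHT_KG
) -> HumanPrediction:
    """Tang–Mayersohn prediction from species records (coefficient via SA)."""
    sa = simple_allometry_cl(records)
    rat = next((r for r in records if r.species == "rat"), None)
    if rat is None:
        raise ValidationError("Tang–Mayersohn requires a rat record")
    a_ml_min = sa.coefficient * 1000.0 / 60.0  # L/h at 1 kg -> mL/min
    cl = tang_mayersohn_cl(a_ml_min, rat.fu_plasma, human.fu_plasma, human_bw)
    return HumanPrediction(method="TME", cl=cl, fit=sa)


def _oie_tozer_forward(fu: float, fu_t: float, volumes: tuple[float, float, float], re_i: float) -> float:
    vp, ve, vr = volumes
    return vp * (1.0 + re_i) + fu * vp * (ve / vp - re_i) + vr * fu / fu_t


def oie_tozer_vss(
    records,
    human: SpeciesRecord,
    volumes: dict[str, tuple[float, float, float]] | None = None,
    re_i: float = RE_I_RATIO,
) -> HumanPrediction:
    """Human Vss by the Øie–Tozer model.

    For each animal the tissue unbound fraction fu_t is solved from
    Vss = Vp(1+RE/I) + fu·Vp(Ve/Vp − RE/I) + Vr·fu/fu_t; the species mean
    fu_t is applied forward with human physiological volumes and human fu.
    Species whose solved fu_t is non-positive are excluded with a warning.
    """
    volumes = volumes or OIE_TOZER_VOLUMES
    fu_ts = []
    for rec in _animal_records(records):
        vp, ve, vr = volumes[rec.species]
        vss = _need(rec, "vss_obs")
        denom = vss - vp * (1.0 + re_i) - rec.fu_plasma * vp * (ve / vp - re_i)
        fu_t = vr * rec.fu_plasma / denom if denom != 0 else np.inf
        if not np.isfinite(fu_t) or fu_t <= 0:
            logger.warning("Øie–Tozer: species %s solved fu_t=%.3g, excluded", rec.species, fu_t)
            continue
        fu_ts.append(fu_t)
    if not fu_ts:
        raise ValidationError("Øie–Tozer: no species yielded a positive tissue unbound fraction")
    fu_t_mean = float(np.mean(fu_ts))
    vss_h = _oie_tozer_forward(human.fu_plasma, fu_t_mean, volumes["human"], re_i)
    return HumanPrediction(method="OT", vss=vss_h)


def dog_proportionality_vss(v_dog: float, fu_human: float, fu_dog: float) -> float:
    """Human Vss from the dog value scaled by the fu ratio: V_dog·fu_hu/fu_dog."""
    for name, v in (("v_dog", v_dog), ("fu_human", fu_human), ("fu_dog", fu_dog)):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0")
    return v_dog * fu_human / fu_dog


def halflife(cl: float, vss: float) -> float:
    """Plasma i.v. elimination half-life ln(2)·Vss/CL (h)."""
    if cl <= 0 or vss <= 0:
        raise ValidationError("cl and vss must be > 0")
    return float(np.log(2.0) * vss / cl)


def combine_predictions(predictions) -> HumanPrediction:
    """Mean ± sample SD of CL and Vss across scaling methods.

    Methods labeled ``PBPK`` or ``IVIVE`` are excluded from the mean (they
    are mechanistic, not scaling, estimates). With a single contributing
    value the SD is undefined (None).
    """
    preds = [p for p in predictions if p.method.lower() not in ("pbpk", "ivive")]
    if not preds:
        raise ValidationError("no predictions to combine")
    cls = np.array([p.cl for p in preds if p.cl is not None], dtype=float)
    vsss = np.array([p.vss for p in preds if p.vss is not None], dtype=float)
    if cls.size == 0 and vsss.size == 0:
        raise ValidationError("no CL or Vss values to combine")
    cl = float(cls.mean()) if cls.size else None
    vss = float(vsss.mean()) if vsss.size else None
    cl_sd = float(cls.std(ddof=1)) if cls.size > 1 else None
    vss_sd = float(vsss.std(ddof=1)) if vsss.size > 1 else None
    t_half = halflife(cl, vss) if (cl and vss) else None
    return HumanPrediction(method="mean", cl=cl, vss=vss, t_half=t_half, cl_sd=cl_sd, vss_sd=vss_sd)


def predict_all(records, human_bw: float = HUMAN_BODY_WEIGHT_KG) -> list[HumanPrediction]:
    """Run every scaling method on a species table and append their mean.

    ``records`` must include the human in vitro record plus animal records
    with observed in vivo PK. Returns per-method predictions (with derived
    half-lives where both CL and Vss exist within a row-pairing convention)
    followed by the combined mean.
    """
    human = next((r for r in records if r.species == "human"), None)
    if human is None:
        raise ValidationError("records must include a human entry")
    dog = next((r for r in records if r.species == "dog"), None)
    preds = [
        nas_fub_cl(records, human, human_bw),
        tang_mayersohn_from_records(records, human, human_bw),
        rule_of_exponents_cl(records, human_bw),
        sa_fub_vss(records, human, human_bw),
        oie_tozer_vss(records, human),
    ]
    if dog is not None:
        preds.append(
            HumanPrediction(
                method="dog_proportionality",
                vss=dog_proportionality_vss(_need(dog, "vss_obs"), human.fu_plasma, dog.fu_plasma),
            )
        )
    preds.append(combine_predictions(preds))
    return preds
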