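"""Non-compartmental analysis of concentration-time profiles.

AUC uses the linear-up / log-down trapezoidal rule; the terminal slope
(lambda_z) is selected by best adjusted-R² over contiguous terminal windows
of at least three points, excluding tmax. AUMC applies the same trapezoidal
convention to the first-moment curve t·C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConcProfile, ValidationError

__all__ = ["NCAResult", "auc_lin_up_log_down", "nca_iv", "nca", "bioavailability"]

#: AUC extrapolated beyond the last sample above this fraction flags the result.
EXTRAPOLATION_WARN_FRACTION = 0.20


@dataclass(frozen=True)
class NCAResult:
    """Model-free PK metrics for one profile.

    ``cl`` (L/h/kg) and ``vss`` (L/kg) are only meaningful for i.v. data and
    are None for oral profiles. ``extrapolation_warning`` is set when more
    than 20% of AUC_inf is extrapolated beyond the last sample.
    """

    auc_last: float
    auc_inf: float
    lambda_z: float
    t_half: float
    cmax: float
    tmax: float
    cl: float | None = None
    vss: float | None = None
    mrt: float | None = None
    n_lambda_z: int = 0
    extrapolation_warning: bool = False


def _trapezoid_lin_up_log_down(times: np.ndarray, values: np.ndarray) -> float:
    """Lin-up/log-down trapezoid of ``values`` over ``times``.

    Linear trapezoid when the segment rises (v2 >= v1) or touches zero;
    log trapezoid (v1 − v2)·Δt / ln(v1/v2) on declining all-positive segments.
    """
    total = 0.0
    for t1, t2, v1, v2 in zip(times[:-1], times[1:], values[:-1], values[1:]):
        dt = t2 - t1
        if v2 < v1 and v1 > 0 and v2 > 0:
            total += (v1 - v2) * dt / np.log(v1 / v2)
        else:
            total += 0.5 * (v1 + v2) * dt
    return float(total)


def auc_lin_up_log_down(times, concs) -> float:
    """Area under the concentration-time curve up to the last sample (ng·h/mL)."""
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.size < 2:
        raise ValidationError("AUC requires at least 2 points")
    if not np.all(np.diff(times) > 0):
        raise ValidationError("times must be strictly increasing")
    if np.any(concs < 0):
        raise ValidationError("concentrations must be >= 0")
    return _trapezoid_lin_up_log_down(times, concs)


def _fit_lambda_z(times: np.ndarray, concs: np.ndarray) -> tuple[float, float, int]:
    """Terminal log-linear regression.

    Returns (lambda_z, intercept on the ln scale, n points used). Candidate
    windows are all contiguous terminal spans of >= 3 positive-concentration
    points that start after tmax; the window with the highest adjusted R²
    wins. Raises ValidationError when no window has a negative slope.
    """
    i_max = int(np.argmax(concs))
    best = None
    n = times.size
    for start in range(i_max + 1, n - 2):
        idx = np.arange(start, n)
        c = concs[idx]
        if np.any(c <= 0):
            continue
        x, y = times[idx], np.log(c)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= 1.0e-20:  # flat on the log scale: no decline to regress
            continue
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(resid**2))
        r2 = 1.0 - ss_res / ss_tot
        m = idx.size
        adj_r2 = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if best is None or adj_r2 > best[0]:
            best = (adj_r2, -slope, intercept, m)
    if best is None:
        raise ValidationError("lambda_z undefined: no terminal window with a negative slope")
    _, lz, intercept, m = best
    return lz, intercept, m


def nca_iv(profile: ConcProfile, dose: float) -> NCAResult:
    """NCA of an i.v. profile: AUC, lambda_z, t1/2, CL, Vss, Cmax/tmax.

    ``dose`` is in mg/kg; AUC extrapolation to infinity uses C_last/lambda_z,
    CL = dose/AUC_inf and Vss = CL·MRT with MRT = AUMC_inf/AUC_inf.
    """
    if dose <= 0:
        raise ValidationError("dose must be > 0")
    t, c = profile.times, profile.concs
    if t.size < 3:
        raise ValidationError("NCA requires at least 3 points")

    lambda_z, _, n_lz = _fit_lambda_z(t, c)
    auc_last = auc_lin_up_log_down(t, c)
    aumc_last = _trapezoid_lin_up_log_down(t, t * c)
    c_last, t_last = float(c[-1]), float(t[-1])
    auc_tail = c_last / lambda_z
    aumc_tail = c_last * t_last / lambda_z + c_last / lambda_z**2
    auc_inf = auc_last + auc_tail
    aumc_inf = aumc_last + aumc_tail

    mrt = aumc_inf / auc_inf
    # dose mg/kg over AUC ng·h/mL = µg·h/L: CL = dose*1e3 (µg/kg) / AUC -> L/h/kg
    cl = dose * 1.0e3 / auc_inf
    vss = cl * mrt
    i_max = int(np.argmax(c))
    return NCAResult(
        auc_last=auc_last,
        auc_inf=auc_inf,
        lambda_z=lambda_z,
        t_half=float(np.log(2.0) / lambda_z),
        cmax=float(c[i_max]),
        tmax=float(t[i_max]),
        cl=cl,
        vss=vss,
        mrt=mrt,
        n_lambda_z=n_lz,
        extrapolation_warning=auc_tail / auc_inf > EXTRAPOLATION_WARN_FRACTION,
    )


def nca(profile: ConcProfile, dose: float, route: str = "iv") -> NCAResult:
    """Route-aware NCA. Oral profiles get AUC/lambda_z/Cmax only (no CL/Vss)."""
    if route == "iv":
        return nca_iv(profile, dose)
    if route != "oral":
        raise ValidationError(f"unknown route {route!r}")
    res = nca_iv(profile, dose)
    # CL and Vss are confounded with F after oral dosing.
    return NCAResult(
        auc_last=res.auc_last,
        auc_inf=res.auc_inf,
        lambda_z=res.lambda_z,
        t_half=res.t_half,
        cmax=res.cmax,
        tmax=res.tmax,
        cl=None,
        vss=None,
        mrt=None,
        n_lambda_z=res.n_lambda_z,
        extrapolation_warning=res.extrapolation_warning,
    )


def bioavailability(auc_po: float, dose_po: float, auc_iv: float, dose_iv: float) -> float:
    """Absolute oral bioavailability F = (AUC_po/dose_po) / (AUC_iv/dose_iv).

    Values above 1 are returned as computed (the caller may cap for
    reporting); all inputs must be positive.
    """
    for name, v in (("auc_po", auc_po), ("dose_po", dose_po), ("auc_iv", auc_iv), ("dose_iv", dose_iv)):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0")
    return (auc_po / dose_po) / (auc_iv / dose_iv)
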