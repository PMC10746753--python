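# Methods

This note documents the models, conventions and numerical choices behind
`transpkpd`, and what the synthetic-data-based tests do and do not
demonstrate.

## Units and fixture data

All quantities use fixed package-wide units: time in h, plasma and
effect-site concentrations in ng/mL, doses in mg/kg (animals) or mg with an
explicit body weight (humans), clearance in L/h/kg, volumes in L/kg, and
the Met-EF1α biomarker in µg per mg total tumor protein. The mg/L → ng/mL
factor of 1000 is applied inside the model code.

The species tables shipped in `core.py` are literal transcriptions of the
published in vitro (unbound CLint in hepatocytes and microsomes, median fu
at 5 µM, blood-to-plasma ratio) and in vivo (body weight, CL, Vss, F) means
for mouse, rat, monkey, dog and human, together with the mouse xenograft
PK/PD estimates (ka 2.7 h⁻¹ fixed; CL/F 0.415 L/h/kg; V/F 1.034 L/kg;
ke0 0.0566 h⁻¹; kin 29.1 µg/mg/h; kout 1.45 h⁻¹; Imax 0.91; IC50
340 ng/mL). The 5 µM-median fu column is used by every scaling method; the
published analysis is ambiguous about the fu choice for the Tang–Mayersohn
method, which is why its reported value is only approximately reproduced
and the fu inputs are explicit arguments. The compound molar mass
(386.36 g/mol) is stored as derived from the printed 340 ng/mL ↔ 0.88 µM
equivalence. Human body weight defaults to 70 kg and is overridable.

## IVIVE

In vitro unbound intrinsic clearance is scaled to whole-body CLint with
hepatocellularity (10⁶ cells/g liver) or microsomal protein (mg/g liver)
and liver weight (g/kg body weight), then converted to hepatic plasma
clearance by

CL_H = Qh·fu·CLint / (Qh + fu·CLint/(B/P)).

This printed algebra is the well-stirred form; because the source describes
the approach as a parallel-tube blood-flow model, a true parallel-tube
option (CL_blood = Qh·(1 − e^(−fu·CLint/(Qh·B/P))), returned as plasma
clearance via B/P) is available behind `model="parallel-tube"` for
sensitivity analysis. The Hallifax–Houston microsomal-binding correction
fu_inc = 1/(1 + P·10^(0.072·logD² + 0.067·logD − 1.126)) is exposed as a
general utility; the compound's logD is not part of the fixture data, so
the shipped microsomal CLint values are used as-is.

Default physiological constants: human hepatocellularity 99×10⁶ cells/g,
microsomal protein 40 mg/g, liver 24.4 g/kg, Qh 1.16 L/h/kg. The scaling
constants used by the original proprietary software are not published, so
the animal defaults (mouse 110/45/55/5.40, rat 117/44.8/36.6/3.31, monkey
120/45/34/2.62, dog 215/55.4/32.9/1.85, in the same order of fields) were
fixed once, within published physiological ranges, such that default
hepatocyte-based predictions reproduce the reported cross-species
concordance of roughly 0.5–3-fold against observed clearances. All
constants are overridable per species.

## Allometry

All regressions are ordinary least squares of log10(absolute quantity) on
log10(body weight) over the four animal species means, in base-10 logs;
the reported R² is that of the log-scale regression. Method conventions:

* **NAS_fub (CL):** per species (CL/fu)·(CLint_mic,human/CLint_mic,species)·BW,
  regress, predict at 70 kg, multiply by human fu, divide by 70. This
  interpretation reproduces the published 0.022 L/h/kg and R² ≈ 0.986 from
  the printed means.
* **SA_fub (Vss):** (Vss/fu)·BW, same back-transformation; exponent ≈ 0.98.
* **Rule of exponents:** simple allometry of absolute CL; exponent < 0.71
  keeps plain allometry (the case here, b ≈ 0.58), 0.71–1.0 uses the
  maximum-lifespan-potential product, > 1.0 the brain-weight product. MLP
  and brain-weight constants are standard comparative-physiology values
  shipped as documented tables.
* **Tang–Mayersohn:** CL_human(mL/min) = 33.35·(a/Rfu)^0.77 with a the
  simple-allometry coefficient at 1 kg in mL/min and Rfu = fu_rat/fu_human.
* **Øie–Tozer:** the tissue unbound fraction fu_t is solved per species from
  Vss = Vp(1 + RE/I) + fu·Vp(Ve/Vp − RE/I) + Vr·fu/fu_t, averaged, and
  applied forward with human volumes. The physiological volume set is a
  standard literature table (RE/I = 1.4); species solving to non-positive
  fu_t are excluded with a warning.
* **Half-life:** computed as t1/2 = ln(2)·Vss/CL. (The source prints the
  algebra with CL and Vss interchanged, which is dimensionally inconsistent
  and does not reproduce its own 7.3 h result; the form used here does.)
* **Combination:** arithmetic mean ± sample SD across the scaling methods;
  PBPK/IVIVE-type estimates are excluded from the default mean, matching
  the convention that only the scaling methods feed the human simulation.

## NCA

AUC uses the linear-up/log-down trapezoid (linear when the segment rises or
touches zero, logarithmic on positive declines). The terminal slope λz is
chosen by best adjusted R² over all contiguous terminal windows of ≥ 3
positive points after tmax — the vendor software's selection rule is not
published, so this standard convention is documented as deliberate. AUMC
applies the same segment rule to the first-moment curve t·C, with the usual
tail corrections C_last/λz and C_last·t_last/λz + C_last/λz². CL = dose/AUC∞,
Vss = CL·AUMC∞/AUC∞ (i.v. only); results with > 20% extrapolated AUC carry a
warning flag.

## PK/PD model and simulation

The oral one-compartment concentration is evaluated in closed form and
superposed across doses with partial geometric sums, so the forcing
function of the PD system is exact. The effect-site concentration also has
an analytic tri-exponential form used for cross-checking and fast fitting.
Degenerate rate constellations (ka ≈ ke, ke0 ≈ ke, …) switch to limit
formulas through a stable (1 − e^(−x))/x evaluation.

The reference simulation integrates (Ce, E) with LSODA at rtol 1e-8 /
atol 1e-10, split at dose times, from Ce(0) = 0 (the initial effect-site
concentration is not stated anywhere; zero is the standard effect-
compartment convention) and E(0) = kin/kout. Output is a 0.1 h grid by
default. The fitting path instead uses a fixed-grid exponential integrator
on the scalar biomarker equation (linear in E given Ce): per step,
E ← E·e^(−ā·h) + kin·h·(1 − e^(−ā·h))/(ā·h) with the midpoint decay rate ā.
This is deterministic and smooth in the parameters — adaptive solvers
introduce step-selection noise into finite-difference Jacobians — and
agrees with the reference path to ≈0.1% at the default 0.1 h step.

Steady state is declared when the interval-to-interval change of both the
trough concentration and the biomarker minimum falls below 0.1% (a
convention; the source is silent), with a hard cap of 10 PK half-lives plus
10/ke0 hours.

## Estimation

Because every animal contributes a single terminal sample, the data are
naive-pooled (population approaches reportedly failed to converge on these
data). Both fits minimize log-scale residuals (multiplicative error), with
log-parameterization (logit for Imax) enforcing positivity and bounds. The
optimizer is trust-region-reflective least squares with five jittered
starts from a fixed internal seed. The PD fit is sequential: concentrations
entering the effect compartment are PK-model predictions, never
observations. ka is fixed at 2.7 h⁻¹ by default (its provenance is not
given in the source, so it is configuration, not hard-coded).

−2LL, AIC and BIC come from the Gaussian likelihood on the log scale with
the residual variance profiled out (one extra counted parameter). CV% is
the Jacobian-based asymptotic relative standard error; the covariance is
computed through the SVD of the Jacobian so that uninformed directions
yield exploding CV% (the non-identifiability flag) instead of being
silently truncated.

## Synthetic data

The generator emulates the destructive-sampling designs: single-dose and
4-day repeat-dose studies at 10/25/100 mg/kg sampled at 1, 7, 24, 48, 72
and 96 h with 5 animals per time point, and a 6-week daily study sampled 1,
7 and 24 h after the last dose. Observations are model predictions times
lognormal noise with median 1 and natural-scale CV equal to `noise_cv`
(default 0.2 — a typical preclinical assay spread; the true residual
magnitudes of the assays are not reported). Concentration and biomarker
errors are independent; regeneration is bit-identical per seed.

What the generator does **not** emulate: inter-animal PK/PD variability
(consistent with the pooled estimation strategy, available as a non-goal
extension), assay quantification limits (very low late concentrations are
reported as-is, which makes the terminal phase easier to estimate than in
real studies), tumor-size dynamics, and correlated within-animal errors.
Passing recovery tests therefore show correctness of the estimation
machinery under the stated noise model, not robustness to all features of
real xenograft data.

## Translation

The PD target is the steady-state biomarker minimum of the minimal
efficacious mouse regimen (25 mg/kg twice daily, E_min ≈ 132 µg/mg) rounded
down to a 25 µg/mg granularity, reproducing the round published target of
125 µg/mg. (A 5 µg/mg granularity would give 130 and does not match the
published threshold; the coarser granularity is the package default.)

The human projection uses CL 0.020 L/h/kg, Vss 0.21 L/kg, F 0.6
("at least 60%"), ka 0.35 h⁻¹ and 70 kg by default, all explicit
configuration. The dose search walks a 5 mg grid with bracketing and
bisection; monotonicity of E_min in dose makes this exact on the grid. A
closed-form steady-state trough (geometric accumulation of the
biexponential) backs the simulated trough to within 0.5%.

The published human projection paired 150 mg once daily with a
1500 ng/mL steady-state trough, but its absorption arm came from a
proprietary physiologically based model that is not reconstructible from
the printed information. The package therefore documents a sensitivity scan
over F ∈ [0.6, 0.8] and body weight ∈ [60, 70] kg: the trough required for
the PD target is nearly absorption-independent (≈1.58–1.63 µg/mL,
within 10% of the published value), while the required dose spans
165–250 mg, approaching the published dose at the favorable corner.

## Problem sizes

The recovery experiments use ten synthetic study pairs (20% CV, 5 animals
per time point, 180 concentration and 180 biomarker observations per pair),
a size at which the median estimates are stable to a few percent.
Steady-state simulations run 14 days of twice-daily dosing (mouse) or until
the 0.1% convergence rule fires (human, typically 10–12 daily intervals).

## Known limitations

* The effect-compartment IC50 is a model construct, not a measured
  tissue concentration; its interpretation is regimen-dependent.
* Only oral first-order absorption PK is implemented (no i.v. infusion
  PD simulations, lag times, nonlinearity or time-dependent clearance).
* The Øie–Tozer and Tang–Mayersohn reproductions depend on unpublished
  constant/fu choices and are exposed with explicit inputs rather than
  asserted against the published third decimals.
* Human projections inherit every uncertainty of the predicted clearance;
  a small absolute error in a 0.02 L/h/kg clearance moves the projected
  dose substantially.
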