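# Methods

## Scope and quantities

capsorb models equilibrium and kinetic water sorption of a hygroscopic
solid (the motivating system is a gelatin capsule shell) and derives the
differential thermodynamics of the process. All moisture quantities are
percent mass change *per unit shell mass*: raw capsule masses are
normalised by the skin mass fraction `M_fs` (shell mass / whole-capsule
mass) because the fill does not sorb water. Water activity `a_w` is a
dimensionless fraction (RH %/100 at equilibrium); every isotherm formula
takes `a_w`, never RH %. Temperatures are absolute (K) in all
thermodynamic formulas; `celsius_to_kelvin` adds 273.15.

## Isotherm models

Five models (GAB, Peleg, Smith, Halsey, Henderson) are evaluated exactly
as their standard displayed forms, with these conventions:

* **Smith** is `y = a + b·ln(1−a_w)` taken literally. For materials whose
  uptake grows with humidity the fitted `b` is negative (e.g. the 25 °C
  reference fit `a = −8.05`, `b = −17.01`); no re-parameterisation is
  applied.
* **GAB** requires `0 < k ≤ 1`, `c > 0`, `x0 > 0` and poles at
  `a_w = 1/k`; evaluation is restricted to `a_w < 1/k`.
* **Halsey** is undefined at `a_w = 0` (log pole) but has limit 0 there;
  range computations use that limit, evaluation raises a domain error.

Inversion (needed to hold EMC constant across temperatures in the
isosteric analysis) uses closed forms where they exist — Smith:
`a_w = 1 − exp((y−a)/b)`; GAB: the quadratic
`y(1−c)u² − (y(2−c)+c·x0)u + y = 0` in `u = k·a_w`, keeping the root with
`u ∈ (0,1)` (the smaller if ever both qualify, guarded although
impossible for `c > 1`) — and bracketed root finding (Brent) on the
forward formula for Peleg, Halsey and Henderson, to better than 1e−9 in
EMC. The default upper bracket is `a_w = 0.9999`
(`min(0.9999, 1/k − 1e−9)` for GAB).

A note on scale: the published 32 °C GAB reference fit carries
`x0 = 177.03`, two orders of magnitude above the neighbouring Smith-model
EMC values, and its units are ambiguous in the source table. The package
uses printed parameters exactly as printed wherever they appear
(evaluation, inversion, recovery round trips) and makes no correction;
only the *demo truth* of the synthetic generator substitutes a
physically coherent `x0` (below).

## Kinetic models

Zero-order, first-order `a(1−e^{−bt})`, second-order `ab²t/(1+abt)` and
biexponential `A1·e^{−t/c} + A2·e^{−t/d} + y0`, with time in hours
(weighings every 0.5 h in the emulated protocol). The biexponential is
kept exactly as written; negative fitted amplitudes are allowed (a rising
uptake curve needs them). `time_to_fraction` inverts the first-order
model analytically, `t_f = −ln(1−f)/b`.

## Fitting and model selection

Ordinary (unweighted) least squares; no error weighting is applied
because the emulated protocol reports only mean ± SD per point.
Minimisation uses a bounded trust-region-reflective solver
(`scipy.optimize.least_squares`) with `xtol = ftol = gtol = 1e−14` and at
most 10 000 evaluations per start — tight tolerances are needed for the
1e−5-relative parameter-recovery guarantees the tests enforce. The GAB
and Peleg objectives are multimodal, so every fit is a multi-start: a
deterministic, data-scaled grid per model (e.g. GAB:
`k ∈ {0.5, 0.7, 0.9} × c ∈ {1, 10, 50} × x0 ∈ max(EMC)·{0.5, 1, 5}`;
Smith and zero-order start from their exact linear-algebra solutions;
Halsey/Henderson add a log-linearised start) is extended with seeded
log-normal perturbations up to `n_starts` (default 16), and the best
converged objective wins. Because starts are consumed as a deterministic
prefix, raising `n_starts` can never worsen the objective.

Kinetic fits prepend the implicit anchor `(t = 0, Mgr = 0)` by default
(`include_time_zero=False` switches it off): the weighing protocol starts
at 0.5 h but the sample demonstrably starts dry. Recovery tests that
sample a model which does not pass through the origin (zero-order,
biexponential) disable the anchor.

Goodness of fit is `RSS = Σ(y−ŷ)²` and `R² = 1 − RSS/TSS` (TSS about the
mean). Selection picks the highest R², with ties at 4 decimal places (the
precision of the reference tables) broken by lower RSS, then fewer
parameters, then model name — the last rule only to make the choice
independent of input order. R² is the operative criterion: in the
reference study Smith beats GAB at 25 °C on R² despite a larger RSS.
Asymptotic standard errors come from the Jacobian at the optimum,
`cov = (JᵀJ)⁻¹·RSS/(n−p)`; they are labelled as such and are not claimed
to match the ± values of replicate-based tables.

## Thermodynamic chain

* `ΔG = −R·T·ln a_w` (J/mol), with `R = 8.314 J/(mol·K)`.
* Isosteric analysis: for each EMC on a grid, each temperature's selected
  isotherm is inverted to `a_w(T)` and `ln a_w` is regressed on `1/T`;
  `q_st = −R·slope` (net isosteric heat, J/mol; reported as kJ/mol in
  displays) and `ΔS_d = R·intercept`. With exactly two temperatures the
  regression is exact and its R² ≡ 1; with three there is one residual
  degree of freedom, so the per-point `fit_r2` is recorded but never used
  for gating. No sign constraint is placed on `ΔS_d`.
* Default EMC grid: 20 evenly spaced values on the *intersection* of the
  per-temperature attainable EMC ranges over `a_w ∈ [0.43, 0.92]` (the
  emulated humidity span), shrunk by a hair so endpoints stay strictly
  invertible. Grid size and activity span are caller-configurable.
* Spreading pressure `φ = (k_B T/A_M)·ln((1−k a_w+k c a_w)/(1−k a_w))`
  with `k_B = 1.38e−23 J/K` and `A_M = 1.06e−19 m²`. It always uses GAB
  constants: the pipeline fits GAB at every temperature even where
  another model was selected, and uses each temperature's own constants.
* Compensation: OLS of `q_st` on `ΔS_d` gives `T_β` (slope, K) and
  `ΔG_β` (intercept). `ΔG_β` is carried in J/mol — the intercept of a
  J/mol-vs-J/(mol·K) line is dimensionally J/mol, although source
  material sometimes prints J/(mol·K) for it. `T_hm = N/Σ(1/T_i)`.
  Driving force: enthalpy if `T_hm < T_β`, entropy if `T_hm > T_β`;
  when `|T_β − T_hm| ≤ 1 K` (configurable) the theory is flagged not
  applicable and the report prints "indeterminate".

## Synthetic studies

`StudyConfig` encodes the emulated design: temperatures 25/32/37 °C, the
six-salt humidity ladder (K₂CO₃, KBr, KI, NaCl, KCl, Na₂CO₃ — the
tabulated RH values are kept exactly as published, including Na₂CO₃'s
97% at 37 °C), kinetics at 68% RH sampled half-hourly over 0.5–6 h, and
additive homoscedastic Gaussian noise on EMC/Mgr (default sd 0; a
heteroscedastic mode with sd proportional to signal exists but is off by
default, since the emulated protocol gives no error model). Each reported
point is the mean of `replicate_count` noisy weighings. Generators are
pure functions of `(config, seed)`.

The default truth is Smith(−8.05, −17.01) at 25 °C, Smith(−2.63, −7.98)
at 37 °C and GAB(k = 0.89, c = 13.17, `x0 = 4.0`) at 32 °C. The GAB `x0`
is deliberately *not* the published 177.03 (see the scale note above):
4.0 puts the 32 °C curve on the same EMC scale as its neighbours so the
three attainable ranges overlap and the end-to-end thermodynamic demo
produces coherent curves (q_st ≈ 7–12 kJ/mol over the default grid, the
magnitude typical of biopolymer sorption).

What passing tests show — and what they do not: the generator reproduces
the *statistical structure* of a salt-slurry study (design, noise,
replication), so green tests demonstrate that the estimation machinery
recovers known truths under that structure. Real shells add effects the
generator omits: drift and hysteresis between sorption and desorption,
heteroscedastic and correlated weighing errors, temperature-dependent
M_fs, and matrix changes (cracking, foaming) at high humidity. Data-
dependent published numbers (per-model R²/RSS on real capsules, the
measured q_st maximum of 11.665 kJ/mol) are therefore not reproduction
targets; they are covered qualitatively.

## Problem sizes and numerical choices

Defaults throughout were chosen as the smallest sizes that exercise the
method fully: 6 humidities × 3 temperatures per isotherm study, 12
half-hourly kinetic points, 20-point EMC grids, 16 fitting starts, and
100-seed replication for the unbiasedness property. Degenerate inputs
fail loudly rather than silently: constant observations (zero TSS),
underdetermined fits (n ≤ p), unreachable EMC targets (range error
carrying the attainable interval), empty model lists, sub-absolute-zero
temperatures.

## Known limitations

* Adsorption branch only; desorption hysteresis is out of scope.
* No mechanistic (Fickian/Weibull) kinetics and no BET isotherm (valid
  only below `a_w ≈ 0.45`, beneath the humidity span modelled here).
* AIC/BIC selection and bootstrap intervals are deliberately absent; the
  selection criterion is R²/RSS by design.
* With three temperatures the isosteric regression has a single residual
  degree of freedom; `q_st`/`ΔS_d` uncertainties are not propagated into
  the compensation fit.
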