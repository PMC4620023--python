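# Methods

## Scope and data model

The package evaluates a sustained-release ocular formulation against a
reference solution along four linked stages: (1) in vitro dissolution
kinetics, (2) single-dose ocular pharmacokinetics in aqueous humor,
(3) MIC-anchored PK/PD indices, (4) multiple-dose simulation for
dosing-interval design. Two measurement types feed it: cumulative percent
released vs time (Franz diffusion cell, simulated tear fluid), and drug
concentration in aqueous humor vs time. The in vivo design is destructive —
each animal contributes one eye at one time point — so replicates are
independent across times and the analysis level is the per-time-point mean
(no mixed-effects modelling; with n ≈ 3 eyes per point there is little
information to estimate between-animal variance components anyway).

## Release kinetics

All five dissolution laws are expressed on the cumulative-released axis so
a single R² ranking is meaningful. Two conventions deserve note:

* The first-order law is classically written for drug *remaining*,
  `Q(t) = Q₀e^(−k₁t)`; since the data are cumulative release, the fitted
  form is `released(t) = Q₀(1 − e^(−k₁t))`, and the remaining form stays
  available in `eval_model(..., form="remaining")`.
* The Baker–Lonsdale matrix-diffusion model is implemented in its lumped
  single-exponential form `Q/Q∞ = 1 − (6/π²)e^(−k_BL t)` with
  `k_BL = π²D/r²`; the diffusion coefficient and particle radius are not
  separately identifiable from release data, so only the lumped rate is
  reported. The classical implicit form
  `3/2[1−(1−Q/Q∞)^{2/3}] − Q/Q∞ = kt` is provided as an explicitly named
  alternative (`baker_lonsdale_classical`, inverted numerically per time
  point) but is not in the default candidate set.
* The Korsmeyer–Peppas exponent comes from the one-term power law
  `Q = K·tⁿ` by default, fitted on the first 10 h of the dissolution run
  (the usual window convention; a ≤ 60 %-release window can be imposed by
  the caller instead). A two-term variant `Q₀ + a′tⁿ + b′t^{2n}` with
  radius-absorbing lumped constants exists for sensitivity checks; the
  reported n always comes from the one-term law because the two-term
  exponent is poorly identified on ten points.

Fitting is bounded (non-negative constants) trust-region least squares.
Starting values come from each model's classical linearisation (log-linear
regression for the exponential laws, √t regression for Higuchi, log-log for
the power law), then five deterministic multiplicative perturbations
(×1, ×0.5, ×2, ×0.25, ×4) guard against poor local minima; the best SSE
wins. R² is the plain 1 − SSE/SST without degrees-of-freedom correction —
the convention used when dissolution models are ranked — so adding
parameters can only help, and exact ties (zero-noise nesting, e.g. the
power law with n = ½ reproducing Higuchi) break toward the model with fewer
parameters. Degenerate profiles (constant release, SST = 0) are rejected
rather than scored.

Mechanism thresholds for spherical matrices: n < 0.45 Fickian,
0.45 ≤ n < 0.89 anomalous transport, |n − 0.89| ≤ 10⁻⁶ case-II,
n > 0.89 super case-II. Boundaries are half-open; the case-II band is a
numerical tolerance, not a scientific claim of exactness.

## One-compartment ocular PK

The Bateman parameterisation used here is `C(t) = A(e^(−Ke t) − e^(−Ka t))`
with a free amplitude A (μg/mL). Because topical dose, ocular
bioavailability and aqueous-humor volume are not separately known, A is the
identifiable lump of F·Dose·Ka/(V(Ka−Ke)); no attempt is made to unpack it.
When Ka = Ke (relative difference below 10⁻⁹) the limiting form
`A·Ke·t·e^(−Ke t)` is used and Tmax = 1/Ke.

Estimation is the standard two-stage scheme for sparse data: Ke from the
terminal slope of ln C vs t over the last 3 positive samples (count
configurable; the default 10-point schedule leaves a short 6–24 h tail),
amplitude seeded by the back-extrapolated terminal intercept, Ka seeded by
the method of residuals on pre-peak points with a 5×Ke fallback when
feathering fails (fewer than two positive residuals), then joint nonlinear
least squares on (A, Ka, Ke) with non-negativity bounds. The two exponents
are exchangeable in this parameterisation; the fit labels the faster one
Ka. A constructed or user-asserted fit with Ka < Ke (flip-flop, absorption
slower than elimination) is flagged, never reordered.

`calibrate_from_summary(Ka, Ke, Cmax)` solves
`A = Cmax/(e^(−Ke·Tmax) − e^(−Ka·Tmax))` so the reconstructed curve's
analytic peak equals the stated Cmax exactly. This is the bridge from
published summary tables to curve-dependent quantities (areas and times
above thresholds, dosing intervals) when raw profiles were never published.
Published summaries can be internally inconsistent (a printed half-life
that is not ln2/Ke, a rounded Tmax); the package always derives from the
printed rate constants and reports closed-form values alongside, never
reconciling silently — with rounded inputs, curve-derived quantities can
differ from printed ones by several percent.

## NCA

Linear trapezoidal AUC on observed points, with a virtual (0 h, 0 μg/mL)
anchor prepended by default (no drug in aqueous humor before instillation;
disable for non-topical designs). Window cut points interior to a sampling
interval are linearly interpolated, which makes the rule exactly additive
over adjacent windows. AUC₀₋∞ adds Clast/Ke; Clast defaults to the last
observed positive concentration, with a model-predicted option for
summary-mode reconstruction where the observed tail is unavailable.
Log-trapezoidal variants and sparse-sampling variance estimation are out of
scope. AUC₀₋₂₄ is always computed on observed (or synthetic-observed) data,
not on the fitted curve: observed trapezoids and model areas answer
different questions and can legitimately disagree.

## PK/PD indices and dosing interval

MIC₉₀ defaults to 1.22 μg/mL and the redosing threshold to k×MIC₉₀ with
k = 2 — i.e. the next drop is scheduled while the aqueous humor still holds
twice the MIC₉₀ — both plain config values. The Bateman curve is unimodal,
so each sub-peak level is crossed exactly twice; crossings are bracketed
and bisected to 10⁻⁶ h. The area above a threshold is integrated by
composite trapezoid with grid doubling (from 2¹⁰ intervals) until two
successive estimates agree to 10⁻⁶ relative. Duration-above-threshold
indices are evaluated on an open-ended window (at least ten half-lives)
rather than clipped at 24 h, since a sustained formulation can stay above
the MIC past the last sampling time. Conventional efficacy breakpoints for
concentration-dependent agents (Cmax/MIC > 10, AUC₀₋₂₄/MIC > 125) are
reported as boolean flags only.

Each report row carries provenance: "summary" when it is arithmetic on
printed values, "curve" when it needed the reconstructed or fitted curve.

## Multiple-dose simulation

Superposition assumes linear PK and identical doses: the multi-dose profile
is the sum of shifted single-dose curves on a 0.01-h grid. Doses fall at
{0, τ, 2τ, …} ∩ [0, horizon) — a dose scheduled exactly at the horizon is
not counted (this half-open convention is what makes a 28.1-h interval give
3 doses and a 12.8-h interval 6 doses over 75 h). Troughs are read just
before each re-instillation (dose time − grid step); because τ is the
down-crossing of the redosing threshold, the first trough equals that
threshold by construction and later troughs sit slightly above it as doses
accumulate. Per-dose scale factors exist as hooks but default to 1.

## Synthetic data

The concentration generator draws, at each scheduled time, n independent
replicates around a Bateman truth curve with mean-preserving multiplicative
lognormal noise (`σ² = ln(1+CV²)`, observation = truth·e^(σZ−σ²/2)) —
assay error in aqueous humor scales with the level — and censors draws
below the LLOQ (default 0.05 μg/mL, a typical chromatographic lower bound)
to zero. Defaults mirror the emulated in vivo design: sampling at 0.5, 1,
1.5, 2, 3, 4, 5, 6, 12, 24 h, three eyes per point, CV = 10 % (assay error
magnitude is not reported anywhere, so 10 % is a realistic mid-range choice,
exposed in config). The release generator adds Gaussian noise (sd in
percentage points, default 2) to a truth model on an hourly 12-h schedule,
clips to [0, 100] and projects onto the non-decreasing cone by isotonic
regression, since cumulative release cannot decrease. A `biphasic_burst`
preset reproduces the characteristic microsphere shape: ~50 % burst within
minutes (saturating term, 0.05-h time constant) plus a slow power-law rise
to ~90 % at 12 h.

What the generators do *not* emulate: between-animal covariates, Franz-cell
hydrodynamics, corneal permeation physics, correlated assay drift, or
below-LLOQ values reported as positive. Passing recovery tests therefore
demonstrates estimator correctness under the assumed noise structure, not
robustness to real-data pathologies.

## Problem sizes and statistical expectations

The Monte-Carlo recovery studies use 200 replicates (PK) and 100 replicates
(release exponent) of the emulated designs — large enough to pin rates to a
few percent while keeping the default suite fast. Under the 10-point /
3-eye / 10 %-CV design, both rate constants land within 15 % of truth in
roughly 80–87 % of replicates. The release exponent at 2-percentage-point
additive noise is recovered within 5 % in only about half the replicates:
ten hourly points carry a slope sampling error of ≈0.013–0.014 on n, wider
than the ±0.0116 band, so no estimator can do much better — the mechanism
*classification* (Fickian, n < 0.45), which only needs the exponent on the
right side of 0.45, is correct essentially always at this noise level. The
corresponding checks in the test suite state both expectations explicitly.

## Known limitations

* One-compartment, first-order kinetics only; no two-compartment or
  saturable elimination, no population (NLME) estimation.
* R² ranking only for model selection (AIC is easy to add but ranking by
  R² is the convention the pipeline mirrors); no F-tests between models.
* The exponent-threshold classifier assumes spherical-matrix geometry.
* Summary-mode reconstructions inherit the rounding of their inputs;
  quantities derived far down the curve (late crossings, extrapolated
  areas) amplify that rounding.
* Superposition assumes dose-to-dose linearity and no inter-dose
  variability or accumulation-induced clearance change.
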