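# Methods

## Structural model

Oral bepotastine kinetics follow a one-compartment model with first-order
absorption and an absorption lag:

    C(t) = 1000 · D·F·ka / (V·(ka − ke)) · (e^{−ke(t−ALAG)} − e^{−ka(t−ALAG)}),  t > ALAG

with `ke = CL/V`. Units are fixed package-wide — time h, dose mg, volume L,
clearance L/h, concentration ng/mL — and the single 1000× (mg/L → ng/mL)
conversion lives in `pk_core`. The degenerate `ka = ke` case switches to the
limiting form `coef·τ·e^{−kτ}` when `|ka − ke|/ke < 1e−8`; the switch is a
continuity threshold, far below parameter precision. Repeated dosing is pure
superposition (the model is linear), and finite AUC uses the analytic
integral of the profile, not quadrature.

## Population model

Individual parameters are log-normal around allometrically scaled typical
values:

    CL_i = θ_CL · (WT_i/70)^0.75 · e^{η_CL,i}      V_i = θ_V · (WT_i/70)^1 · e^{η_V,i}

with KA and ALAG weight-independent. The exponents 0.75 and 1.0 are fixed
constants of the model, never estimated. Default typical values are the
published bepotastine estimates: θ_KA 4.21 h⁻¹, θ_CL 28.0 L/h, θ_V 103.0 L,
θ_ALAG 0.27 h.

Two reporting conventions exist for IIV magnitudes, and they differ
materially only for KA (112.7%):

* `cv_convention="sd"` (default): ω = CV/100 on the log-SD scale, the usual
  reading of NONMEM output tables (`√ω²·100`).
* `cv_convention="lognormal"`: ω² = ln(1 + (CV/100)²), the exact log-normal
  CV. For CL (22.5%) the two differ by <1%.

The random-effect covariance is structured: only the CL–V (0.65) and CL–ALAG
(0.47) correlations are free; KA is independent and the V–ALAG covariance is
identically zero. Positive definiteness of that structure reduces to
ρ₁² + ρ₂² < 1.

Residual error is combined: `y = f·(1 + ε_prop) + ε_add` with proportional
SD 0.103. The additive component is specified as a *variance* of 0.1, so
σ_add = √0.1 ≈ 0.316 ng/mL by default; `additive_error_as_sd=True` reads the
0.1 as an SD instead, since the printed unit (ng/mL) is ambiguous about
which was meant. The additive term is always fixed, never estimated.

## Synthetic study designs

The simulator emulates the two source trials:

* adults — 32 subjects, one 10 mg tablet, 13 nominal samples at 0, 0.33,
  0.67, 1, 1.33, 1.67, 2, 3, 4, 6, 8, 12 and 24 h;
* children (2–6 y) — 30 subjects, 3 mg dry syrup twice daily, two sparse
  samples after the morning dose of day 5 (the 9th dose, guaranteeing at
  least four days of dosing and effective steady state), drawn uniformly in
  the 0.5–2 h and 6–12 h post-dose windows. The sampled dose and the
  uniform-in-window draw are package choices; the source designs fix only
  "≥4 days" and the two windows.

Demographics are truncated normals matching each cohort's reported
mean (SD) and min–max; the adult cohort is all male, the pediatric cohort
63% male. Pediatric age is integer-uniform on 2–6 with weight log-normal
around the age-group median weights (σ set from the reported 5th–95th
spans), truncated to the observed 13–26 kg. Quantification follows the
assay: LLOQ 1 ng/mL, with pre-dose and below-LLOQ observations excluded
(M1); no likelihood-based BLQ handling.

What the generator does **not** emulate: assay drift or batch effects,
adherence deviations and dosing-time jitter, food effects, between-occasion
variability, or model misspecification (data are generated from the fitted
model family itself). Passing recovery and coverage tests therefore
demonstrates internal consistency of estimator and simulator under the
published design — not robustness of the model to real-data violations.

## FOCE estimation

The marginal likelihood per subject is approximated by the Laplace method at
the conditional mode η̂ with a first-order (Gauss–Newton) Hessian and
interaction (residual variance evaluated at the conditional prediction):

    OFV_i = Σ_j [log(2π v_ij) + r_ij²/v_ij] + η̂'Ω⁻¹η̂ + log|Ω| + log|Ω⁻¹ + Σ_j G_j G_j'/v_j|

with `r = y − f(η̂)`, `v = σ_prop²f² + σ_add²`, `G = ∂f/∂η` (analytic,
via the chain rule on the Bateman derivatives). Interaction is the standard
pairing with a combined error model.

Inner problem — damped Newton over η, batched across subjects with a
shrinking active set. The Newton matrix uses the exact second derivative of
the per-observation deviance in f (clipped from below at 0.2/v to stay
positive definite); model curvature ∂²f/∂η² is the only neglected term.
Convergence: gradient max-norm below 1e−6·(1+|g|), or a per-subject stall
(objective decrease < 1e−9 relative per sweep — the Newton matrix is
approximate, so tail convergence is linear and a stall marks the attainable
precision). Because sparse subjects can have two conditional modes (the
absorption/elimination flip-flop in η_KA), converged modes are probed
against candidate KA etas (±1, ±2) and re-polished if a deeper basin exists;
this makes the objective a deterministic, basin-consistent function of the
population parameters.

Outer problem — L-BFGS-B over log-thetas, log σ_prop and a structured
log-Cholesky factor of Ω in which the V–ALAG covariance constraint
`l32 = −l21·l31/l22` is built in, so every iterate is positive definite with
exactly the reported covariance structure. Finite-difference gradients use a
step of 2e−4 (matched to the inner-solver noise floor), followed by a short
polishing run at step 1e−6 that recovers the final digits on sharp
(low-noise) surfaces. A fit is reported non-converged only when both stages
exhaust their iteration caps while the objective is still moving by more
than 0.01 — far below any OFV threshold used for model comparison. Standard
errors come from a central finite-difference Hessian of the OFV at the
optimum (step 0.01), with the delta method mapping to the natural scale;
RSE% = 100·SE/|estimate|.

Empirical Bayes estimates are the conditional modes at fixed population
parameters; a subject with no observations sits at the prior mode η = 0.
Shrinkage is 100·(1 − SD(η̂)/ω) per effect, undefined (reported absent) when
ω = 0.

### Covariate selection

Candidates are AGE, SCR and eGFR (exponential form, centered at the
observed per-subject median) and SEX (power form) on CL and V; weight is
already structural. Greedy forward selection requires ΔOFV > 3.84 (strict;
p < 0.05, 1 df), backward elimination removes any covariate whose removal
worsens OFV by ≤ 6.63 (p < 0.01). Ties break by candidate order — AGE, SCR,
eGFR, SEX — deterministically. Each candidate fit is multistarted from
coefficient inits {0, ±0.25/SD(covariate)} because correlated IIV can absorb
a covariate effect and leave the single-start fit in a shallow local mode;
the best converged trial is kept, and non-convergent candidates are excluded
from that step and logged in the trace.

## Diagnostics

PRED is the typical-covariate prediction (η = 0); IPRED the prediction at
η̂. CWRES whitens the residual about the FOCE-I linearization:
`E[y] ≈ f(η̂) − Gη̂`, `Cov[y] ≈ GΩG' + diag(v(η̂))`, solved by a triangular
(Cholesky) system per subject; a near-singular covariance is jittered by
1e−10 on the diagonal.

The VPC bins adults by nominal time and children by the two sampling
windows (dosing is uniform within each arm, so no prediction correction is
needed). Observed data and every simulated replicate receive the same LLOQ
exclusion, keeping percentiles comparable. Reported per bin: observed
5/50/95th percentiles, the 90% envelope of each percentile across
replicates, and the central 90% band of the pooled simulated observations;
coverage is the fraction of observations inside that band, with bins holding
fewer than 3 observations excluded.

Prediction error is the mean squared error Σ(OBS−PRED)²/n. The
period-split comparison classifies observations by time-after-dose into the
absorption (0.5–2 h) and elimination (6–12 h) windows and compares two
models' squared-error sets with Welch's t-test by default (squared errors
are heavy-tailed, making the unequal-variance form the safer default);
`equal_var=True` selects the pooled-variance variant. Identical error sets
report p = 1.

## Dose optimization

The reference exposure is a single 10 mg dose in a typical 70 kg adult with
no IIV and no residual error: C_max analytic, AUC_last as the analytic
0–24 h integral. This single-dose, 24 h-truncation convention is what
reproduces the published AUC-based dose row at every weight. For each child
weight the typical parameters follow from allometry, and since exposure is
exactly dose-proportional the continuous matching dose is
`reference / per-mg exposure`, snapped to the 0.1 mg prescribing grid —
equivalent to, but cheaper than, scanning all grid doses for the smallest
absolute difference. Rounding is half away from zero, with the quotient
pre-rounded at 1e−9 to keep binary floating-point representation from
flipping half-way cells. The weight grid is the 22 integers 10–31 kg; the
age-banded table evaluates the same matcher at each age group's median
weight.

For AUC matching the grid dose stays within half a grid step of the closed
form `10·(w/70)^0.75` corrected by the ratio of 24 h truncation factors. The
C_max-based continuous doses sit near x.x5 boundaries at several weights,
so a handful of published C_max cells land one 0.1 mg step away from this
convention; the AUC row is exact everywhere.

## Weibull dissolution input

Formulation release is the Weibull CDF
`W(t) = 1 − exp(−((t−lag)/scale)^shape)` with fitted parameters
(scale, lag, shape) of (85 min, 0, 0.84) for the tablet and
(32.63 min, 28.40 min, 0.55) for the dry syrup; minutes are converted to
hours internally. The default coupling is two-stage — dissolution into gut
solution, first-order permeation `ka`, linear elimination — so the model
reduces exactly to the lagged structural model in the fast-dissolution
limit; the total input lag is the formulation lag plus the structural ALAG.
A `direct_input` flag feeds the dissolution rate straight into the central
compartment instead (dissolution-rate-limited absorption).

Concentrations convolve the dissolution rate with the analytic impulse
response of the chain. The substitution `u = ((s−lag)/scale)^shape` removes
the integrable singularity of the Weibull rate at the lag (shape < 1) and
the smooth integrand is evaluated by adaptive quadrature at relative
tolerance 1e−8. AUC uses a single quadrature against the analytically
time-integrated response. C_max is bracketed on a coarse grid and polished
by bounded scalar minimization (xatol 1e−6).

Gastric-emptying sensitivity: a pure added lag is a time shift in a linear
time-invariant system and cannot change C_max, so the emptying time is
modelled as the mean residence time of a first-order gastric stage in
series with absorption. This disperses the input: C_max falls monotonically
with emptying time while AUC_last(24 h) is nearly unchanged (<2% across
0–60 min for typical parameters) — a directional, not numeric, property.

## Pipeline and reproducibility

`run_pipeline` drives simulate → LLOQ filter → fit → GOF/VPC → dose tables →
gastric sensitivity from one config. A single master seed is expanded into
named per-stage streams via `numpy.random.SeedSequence.spawn`, so stages are
independently reproducible and the artifact bundle is byte-identical for a
fixed config (the pipeline tests assert equal SHA-256 digests).

## Problem sizes

The simulation studies in the test suite use the full two-study design
(32 + 30 subjects) where the check is about that design — parameter
recovery over 20 replicates, VPC coverage with 1000 replicates per arm —
and deliberately smaller cohorts (4–24 subjects, 25–150 VPC replicates)
where only the mechanics of an operation are under test, e.g. stepwise
selection logic or percentile ordering. The likelihood-oracle comparison
uses 1–2-subject instances because adaptive Gauss–Hermite quadrature is the
reference there and tensor-product quadrature only scales to a couple of
dimensions.

## Known limitations

* The estimator is a FOCE-style Laplace approximation; its OFV constant is
  not NONMEM's, so absolute OFVs are not comparable across tools (ΔOFVs
  are).
* Sparse designs leave KA and ALAG weakly identified (high shrinkage); the
  recovery guarantees in the tests concern CL and V.
* BLQ handling is exclusion only; with a higher LLOQ or lower doses a
  likelihood-based method (M3) would be needed.
* The Weibull module covers formulation and gastric-emptying effects on the
  input side only; whole-body physiological modelling (organ compartments,
  transporter kinetics, maturation of renal secretion) is out of scope.
* Between-occasion variability and renal maturation covariates are not
  modelled.
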