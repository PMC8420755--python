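# Methods

`cachexpk` re-implements, as a tested desk-scale pipeline, the population
pharmacokinetic analysis of single-dose pembrolizumab in two murine
cancer-cachexia models (C26 colon carcinoma in CD2F1 mice, Lewis lung
carcinoma in C57BL/6 mice). Pembrolizumab does not bind murine PD-1, so the
study design isolates catabolic (FcRn-governed) clearance of an IgG
monoclonal antibody; tumour-bearing, cachectic animals clear the antibody
faster. The animal data themselves were never deposited, so a synthetic
cohort generator stands in for them: every stage of the pipeline — QC,
non-compartmental analysis (NCA), FOCE-I mixed-effects estimation, stepwise
covariate modelling (SCM) — is exercised against data simulated from the
published parameter estimates, and what the tests establish is that the
*machinery* recovers known generative truths at the study's design and
noise level, not that the published animal results are reproduced.

## Structural model and units

Disposition is a linear two-compartment IV-bolus model parameterized as
clearance CL (mL/day/kg), central volume V1 (mL/kg), intercompartmental
clearance Q (mL/day/kg) and peripheral volume V2 (mL/kg). Everything is
per kg body weight, so body weight cancels; doses are in μg/kg (2 mg/kg →
2000 μg/kg), concentrations in μg/mL, and time is kept internally in days
(clearances are printed per day) while sampling schedules and data files
use hours. The concentration is the closed-form biexponential
`C(t) = dose (A e^{-αt} + B e^{-βt})` with `A + B = 1/V1`; the slow hybrid
root is computed as `αβ/α` to avoid cancellation. Repeated-root kinetics
(α ≈ β, relative separation < 1e-10) are rejected as unsupported input —
they cannot arise for parameters in the ranges this pipeline targets.

## Individual parameters and error model

Individual parameters follow the standard multiplicative construction:

    P_i = θ_P · Π_c (cov_c/median_c)^{β_c} · Π_d (1 + β_d I_d) · exp(η_P)

with power terms for continuous covariates (normalized by population
medians computed from the analysis population, as in the source analysis),
a proportional shift for the dichotomous tumour indicator (an exponential
indicator form is available as a config switch), and log-normal
interindividual variability on CL, V1 and V2 only — IIV on Q is not
estimable under this sparse design and is omitted. Residual error is
additive on log-concentration with SD σ, which coincides to first order
with a proportional error model; σ is reported as an SD (the ε row of the
estimates table).

## Synthetic cohorts

The default design mirrors the study: 135 mice — 28 vehicle and 107
pembrolizumab-dosed (53 at 2 mg/kg, 54 at 10 mg/kg) — split over two
strains and tumour-free/tumour-bearing arms, sampled at 1, 48, 96 h and a
terminal sample drawn 50/50 at 144 or 168 h. A fraction (default 28/107)
of dosed animals receives a partial-IV-dose artifact so that the expected
post-QC analysis population is 79, matching the published accounting.
Vehicle animals carry covariates but no concentration records. Randomness
is a single seeded stream with per-subject substreams, so cohorts are
byte-identical across runs at a fixed seed.

Covariates: total IgG is calibrated to the measured strain distributions
(CD2F1 37.328 ± 15.914 μg/mL, C57BL/6 6.610 ± 2.451 μg/mL; log-normal).
Muscle (gastrocnemius), fat (epididymal), albumin, hepatic Fcgrt
expression ratio and percent body-weight change were published only as
figure panels, so their generator settings are direction-calibrated
defaults (tumour-bearing animals lose muscle, fat, weight and albumin and
down-regulate Fcgrt by configurable multipliers) — plausible magnitudes,
not measured ground truth. Conclusions that depend on those magnitudes
(e.g. exact covariate-selection power) therefore characterize the
machinery under stated conditions, not the animal study.

The partial-dose artifact superposes an IV bolus of fraction f with a
first-order depot absorbing the rest (default ka = 0.5/day, f uniform on
[0, 0.2]). With the study's 4-point schedule a partial dose is only
*detectable* as a rising profile for f below roughly 0.25 — for larger f
the IV fraction dominates the early samples and the curve decreases
monotonically — so the generator draws f in the detectable range; QC then
excludes essentially 100% of artifacts while falsely excluding <2% of
clean noisy profiles.

## QC rule

A profile is excluded when the second concentration exceeds the first
(obvious absorption phase) or when any later successive pair rises by more
than `rel_tol` (noise guard). The difference of two independent
log-residuals has SD σ√2, so the default guard is the 2-sigma rise
`exp(2·0.110·√2) − 1 ≈ 0.365`; at 0.10 — a superficially natural choice —
the false-exclusion rate on clean cohorts is ~8% because heavy IIV
flattens some terminal phases. `rel_tol` is configurable.

## Non-compartmental analysis

λz selection emulates automated "best fit" selection: every contiguous
tail of ≥3 positive observations that excludes the Cmax point is fitted
log-linearly and the tail with the highest adjusted R² wins, ties toward
more points; when no Cmax-excluding tail exists (a 3-point profile), all
tails are admissible. AUC_last is the linear trapezoid from the *first
observation* to the last measurable concentration — no back-extrapolated
t = 0 segment; C0 (log-linear back-extrapolation through the first two
points) is reported separately. AUC_inf adds C_last/λz; CL = dose/AUC_inf,
Vz = CL/λz, T½ = ln2/λz. Group summaries are geometric mean (geometric
CV%, n−1 log-variance) except T½, summarized as median (min, max). BQL
records are dropped and counted. With the sparse 4-point schedule the
first-sample truncation plus extrapolation bias the NCA clearance by <5%
on noise-free data; ~0.2% is the floor for a tuned 20-point schedule under
a linear trapezoid.

## FOCE-I estimation

Each subject's marginal likelihood is approximated by linearizing the
model in η about the conditional mode η̂ (penalized least squares, solved
by a batched damped Gauss–Newton with finite-difference Jacobians;
gradient max-norm < 1e-6 at the reported EBEs, 1e-4 during estimation).
Because the residual SD is constant on the log scale, the "with
interaction" bookkeeping coincides with plain FOCE here. The objective
drops the m·log 2π constant (so only ΔOFV is meaningful) and sums
`log det C_i + r̃_i' C_i^{-1} r̃_i` with `C_i = G Ω G' + σ² I`.

The outer problem runs L-BFGS-B on (log θ, covariate coefficients,
log ω², log σ) inside a wide plausibility box (the box keeps extreme
line-search probes numerically benign; without it a single over-ambitious
step toward σ → 0 produces objective values ~1e13 that break the line
search). The inner solve restarts from η = 0 at every evaluation, making
the objective a pure function of the parameters — warm-starting across
evaluations was observed to introduce hysteresis (the inner problem is
multimodal) that stalled the optimizer. Each start is re-launched from its
end point until the OFV stops improving (bounded restarts), and the
default policy adds two jittered restarts with fixed seeds. `converged`
reflects the optimizer's own success status at the best start.

Standard errors come from the central-difference Hessian of the OFV at
the optimum (covariance = 2 H⁻¹; SE% of a log-parameterized quantity is
100·SE_log by the delta method). Variance components estimated at their
floor contribute no curvature; they are excluded from the inversion and
reported missing, and eigen-directions at the finite-difference noise
floor are dropped. A genuinely indefinite Hessian yields no SEs. η
shrinkage is `100·(1 − SD(η̂)/√ω̂²)` with the n−1 SD.

## Stepwise covariate modelling

Likelihood-ratio tests use χ²(1) (one coefficient per effect). The
univariate screen fits base + one effect per candidate and sorts by ΔOFV.
Forward addition re-screens every remaining candidate against the growing
model each round (full SCM — the sequential ΔOFV trace matches the shape
of the published forward table) and adds the smallest p < α; backward
elimination removes the least-harmful effect while its removal p exceeds α
(the boundary exactly at the χ² threshold is retained), with forced-in
effects (e.g. IgG on Q, which the source analysis retained by choice
despite no IIV on Q) never removed. α = 0.05 for both directions by
default, as in the source procedure; both are configurable. SCM refits use
a single-start, slightly loosened optimizer policy (screening ranks hinge
on ΔOFV gaps of tens of units, far above the ~0.01 optimizer noise).

## Problem sizes and numerical choices in the test-bed

The recovery experiments simulate 5 replicate 79-mouse studies (4 samples
each at 1/48/96/168 h, 2 and 10 mg/kg) from the published structural and
final covariate estimates and refit from neutral initial values (CL 10,
V1 50, Q 30, V2 50; coefficients 0; ω² 0.1; σ 0.2): medians across seeds
recover typical CL and V1 within 15%, IIV CV% on CL within 20 points, and
σ within 10%. Tumour and muscle weight are deliberately confounded in the
generator (tumour causes muscle loss), so their coefficients trade off in
single replicates exactly as the source analysis reports for its own
forward/backward order-dependence; the tumour effect still wins the first
screening round in the majority of 20 seeds. Null-covariate calibration
uses 200 scaled-down studies (8 mice each); the ΔOFV for a pure-noise
covariate is compared with χ²(1) and the α = 0.05 selection rate with its
binomial 99% interval. The full forward+backward procedure is exercised
end-to-end on smaller strong-effect cohorts rather than across a 20-seed
battery, purely a problem-size choice.

## Known limitations

- The generator does not model tumour growth over time, assay error
  structure beyond log-normal noise, FcRn mechanism, or BQL censoring
  (the study's dilution scheme kept samples quantifiable; BQL handling is
  exclusion-with-count).
- FOCE-I is a linearization; its OFV is validated against adaptive
  Gauss–Hermite quadrature only on small single-η problems (|ΔOFV| < 0.5).
- SEs are numerical-Hessian (sandwich-free) estimates and are labelled as
  such; the source publication does not state how its SEs were obtained.
- Ω is diagonal throughout; no covariances between random effects.
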