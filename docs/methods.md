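# Methods

## Structural and statistical model

Vancomycin disposition is described by a one-compartment model with
zero-order infusion input and first-order elimination. Concentrations are
closed-form superpositions of per-dose contributions: during an infusion a
dose contributes `(R0/CL)·(1 − e^{−k(t−t0)})` (R0 the infusion rate, k =
CL/V); afterwards the end-of-infusion value decays mono-exponentially.
The apparent volume is fixed at V = 60.2 L — trough-dominated therapeutic
drug monitoring carries almost no information about the distribution phase,
so V is not estimable from such data and is taken from prior work in the
same population. Clearance carries the covariate model

    CL_typ = cl_tv · Π_c (x_c / center_c)^{β_c} · exp(Σ_b β_b · flag_b)

with continuous covariates as centered power terms and binary covariates as
exponential shifts. Between-subject variability is a single log-normal
random effect on clearance, CL_i = CL_typ · e^{η_i}, η ~ N(0, ω²); ω is
reported as CV% = 100·ω (at ω ≈ 0.21 the distinction between 100·ω and the
exact log-normal CV is below 1%). Residual error is "combined":
Var(ε) = σ₂² + (σ₁·C_pred)², evaluated at individual predictions
(interaction). The additive floor σ₂ dominates near the assay's lower limit;
at high concentrations the error is proportional with CV σ₁.

Renal function enters through two standard equations: creatinine clearance
by Cockcroft–Gault, `(140 − age)·BW / (72·Scr)` (×0.85 for women, mL/min,
no body-surface normalisation), and eGFR by CKD-EPI,
`144·(Scr/a)^b·0.993^age` with sex-specific a (0.7 women / 0.9 men) and a
branch-specific exponent b on either side of Scr = a; the two branches agree
at the breakpoint, so eGFR is continuous in Scr. Serum creatinine is held
internally in mg/dL; µmol/L inputs are divided by 88.4. Renal-function
values are never capped — the neurocritical population genuinely shows
augmented renal clearance — but values above 300 mL/min are logged.

## Likelihood and estimation

The marginal likelihood integrates the single η per subject. The package
follows the FOCE-with-interaction idea: for each subject the conditional
mode η̂_i is located by a coarse grid plus golden-section refinement on
[−6ω, 6ω] (tolerance 1e−8), and a Laplace approximation is taken at the
mode using a finite-difference second derivative. Because a plain Laplace
step leaves an approximation error of order 0.01–0.05 OFV units per subject
at ~1.6 observations per subject — enough to bias the variance partition at
cohort scale — the Laplace factor is refined by adaptive Gauss–Hermite
quadrature centered at the mode and scaled by the mode curvature (9 nodes
by default; 1 node reproduces plain Laplace). Against a dense 10,000-node
Gauss–Hermite oracle the objective agrees to ~1e−3 OFV units on a
5-subject fixture. The reported OFV is −2·log marginal likelihood without
the n·log 2π constant, so only OFV differences are meaningful.

The outer problem maximises over (cl_tv, β…, ω, σ₁, σ₂) with positivity
enforced by log transforms, using Nelder–Mead (adaptive simplex; default
fatol 1e−4, at most 2000 evaluations). Initial fixed effects come from a
log-linear regression of naive per-subject clearance (daily dose rate over
mean observed concentration) on the covariate design; variance components
start at ω = 0.3, σ₁ = 0.2, σ₂ = 2 mg/L. Standard errors are Wald:
a central finite-difference Hessian of the OFV on the natural parameter
scale (relative step 5e−3), covariance 2·H⁻¹, 95% CI = estimate ± 1.96·SE.
σ uncertainty is reported on the SD scale. Shrinkages follow the usual
definitions: η-shrinkage = 1 − SD(η̂)/ω̂, ε-shrinkage = 1 − SD(IWRES).
Observations flagged below the lower limit of quantification are excluded
from the likelihood (no M3-style censored likelihood). Conditional weighted
residuals (CWRES) use the first-order expansion of the model about η̂,
whitened by the implied marginal covariance.

## Covariate selection

Candidates are the seven continuous covariates (age, height, body weight,
BMI, Scr, CLcr, eGFR) and five binary ones (sex, RRT, mannitol, meropenem,
diuretics), all acting on CL with the same functional forms as the final
model. Forward addition accepts one covariate per step — the largest OFV
drop, provided it exceeds 6.64 (χ², p < 0.01, df 1; ties break by candidate
order) — then backward elimination removes, weakest first, any covariate
whose removal raises the OFV by at most 10.83 (p < 0.001). The three
renal-function measures quantify the same physiology and are mutually
exclusive by default (a config flag): once one enters, the others leave the
pool. Centering constants for candidates default to dataset medians; the
final published model freezes them at eGFR = 115.2 mL/min and BW = 70 kg so
that its arithmetic is exactly reproducible. Screening fits during the
search use relaxed optimiser tolerances and 5 quadrature nodes — ΔOFV needs
resolution ~1, far coarser than final estimation — and warm-start from the
parent model's estimates.

## Synthetic cohorts

The generator emulates a 560-adult neurosurgical cohort under routine
therapeutic drug monitoring. Age, body weight and height are truncated
normals matching the cohort's mean/SD/range; sex is Bernoulli (66% male);
mannitol, meropenem, diuretics and renal replacement therapy (RRT) are
independent Bernoulli flags at the cohort frequencies (60.3%, 71.3%,
16.0%, 2.7%). Renal function is drawn on the eGFR scale — truncated normal
(115.6, 26) for non-RRT subjects, uniform 4–20 mL/min for RRT subjects,
calibrated so the mixture reproduces the cohort's eGFR mean ≈ 113 and
SD ≈ 31 — and serum creatinine is obtained by inverting CKD-EPI given age
and sex, which induces the age/sex coupling and the right skew of real
creatinine. Two structural couplings are deliberate: Scr depends on
age/sex/eGFR, and the dosing regimen depends on eGFR. All other covariates
are sampled independently, a documented simplification.

Regimens come from the seven in clinical use (0.5 or 1 g at Q6h–Q24h,
1 h infusions) via an eGFR-banded assignment — higher daily dose for better
renal function, reproducing the dose/renal-function confounding of real
prescribing — with band weights calibrated so the mean dose per
administration sits near the cohort's 951 mg. Observation counts per
subject are geometric with mean 1.6; 90% of samples are steady-state
troughs (drawn 3 minutes before a dose, after at least five administered
doses) and the rest fall 2–10 h after the end of a random infusion.
Concentrations are simulated from the model; draws outside the assay's
calibration range (0.67–90 mg/L) are redrawn up to 10 times and then
censor-flagged. The per-subject true η is kept as a sidecar for recovery
tests.

What the generator does *not* reproduce: the observed concentration level
of the real cohort (mean 14.2 mg/L). Under the final model, typical-patient
troughs on the listed regimens sit near 4–9 mg/L; the higher observed mean
in the source data reflects sampling concentrated in patients with reduced
clearance and other selection effects of real monitoring that a
marginal-matching generator cannot induce. Passing recovery and calibration
tests therefore demonstrate correctness of the machinery under the stated
design, not equivalence with the hospital dataset. Relatedly, the assay
floor truncates the lowest troughs of high-clearance subjects; because the
likelihood has no censored-data term, this leaves a small downward bias in
cl_tv and σ₂ (and a compensating upward bias in σ₁) in recovery
experiments. Calibration-style checks (CWRES moments, VPC coverage) are
run with the truncation disabled so they test the estimator rather than
this generator/likelihood mismatch.

## Evaluation

The bootstrap resamples whole subjects with replacement to the original
subject count, refits each replicate (warm-started from the reference fit —
a convergence pragmatic) and summarises converged replicates by median,
2.5–97.5 percentile interval and cross-replicate RSE; fewer than 80%
converged flags the result unstable. The VPC simulates the fitted model on
the dataset's own design (same subjects, doses, times, covariates) with
fresh η and ε, bins observations by quantiles of time-after-last-dose
(8 bins, empty bins merged) and reports 5/50/95 percentile bands plus
pooled coverage — the fraction of observations inside their per-observation
90% prediction interval. Production defaults are 5,000 bootstrap replicates
and 10,000 VPC simulations; the test suite uses 200 and 500 (scaled-down
flags recorded in outputs).

## Dose-finding

For a patient descriptor (eGFR, body weight, mannitol), clearances are
drawn as CL_typ·e^η (1,000 replicates by default) and steady-state exposure
is AUC24_i = daily dose / CL_i exactly; residual (assay) error is not added
because AUC is a model quantity, and the published medians match dose/CL
closed forms to ~1%, confirming that convention. The recommended dose is
the 5 mg grid point whose simulated median AUC24 is nearest the target
(400 or 600 h·mg/L); the same η draws serve all candidate doses, so the
search is exact on the grid and ties go to the smaller dose. Because
median(e^{−η}) = 1, the median AUC24 has the closed form
daily dose / CL_typ, and the 90% interval follows the log-normal quantiles
CL_typ⁻¹·daily·e^{∓1.6449ω}; both are asserted as invariants. Doses above
2,000 mg per administration set an advisory flag suggesting low-dose
intraventricular administration (10–20 mg every 24 h) instead.

## Problem sizes and numerical choices

Default experiment sizes used by the test suite and acceptance script:
parameter recovery at the study scale (560 subjects, ~1.6 obs/subject,
10 seeds), selection consistency at the study scale (5 replicates; the
published mannitol and body-weight effect sizes sit at the chi-square
detection boundary below roughly 300 subjects), null-size control at
300 subjects (5 replicates), bootstrap sanity at 200 subjects ×
200 replicates, VPC calibration at 300 subjects × 500 simulations. These
sizes keep each experiment's Monte Carlo error comfortably inside the
asserted tolerance bands. Degenerate inputs are defined rather than
rejected: ω = 0 collapses the objective to the fixed-effects weighted
least-squares deviance; σ = 0 simulation returns exact model predictions;
a single-replicate VPC yields degenerate but well-defined bands.

## Known limitations

- One compartment only; the distribution phase is invisible in
  trough-dominated data and V is fixed, so peak-phase predictions are
  approximate.
- No censored-data (M3) likelihood; below-LLOQ observations are dropped.
- No inter-occasion variability, time-varying covariates within a subject,
  or random effect on V.
- External (new-cohort) validation is out of scope; evaluation is internal
  (bootstrap, VPC, synthetic-data recovery).
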