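# Methods

## Model and estimation

The structural model is a one-compartment IV bolus,
C_ij = (Dose/V_i)·exp(−(CL_i/V_i)·t_ij), with exponential between-subject
variability on CL and V (diagonal Ω — the simplest model consistent with
"standard exponential BSV"; random-effect correlation is deliberately out of
scope) and a combined residual-error model y = f·(1+ε_p)+ε_a, giving
observation variance g = σ²_prop·f² + σ²_add in the usual first-order form.

The marginal likelihood is approximated by Laplace's method at the
per-subject conditional modes *with interaction*: g is evaluated at each
subject's own η, not at η = 0.  Writing h_i(η) for −2·log of the joint
density of subject i's data and random effects,

    OFV = Σ_i [ h_i(η̂_i) − d·ln 2π + ln det(H_i/2) ],

with η̂_i the minimizer of h_i, H_i its Hessian there, and d the number of
random-effect dimensions.  Dimensions whose ω² is numerically zero
(< 1e−12) are fixed at η = 0 and dropped from the correction, so the OFV
degrades gracefully to the fixed-effects weighted least-squares deviance as
Ω → 0.  The approximation is exact for means linear in η with additive
error, and agrees with 21-node adaptive Gauss–Hermite quadrature to well
under 1% on the dense designs used here (both are asserted by tests).

### Numerics

*Inner problem* (conditional modes): all subjects are solved simultaneously
with a damped Newton iteration on analytic gradients and analytic Hessians,
to a gradient tolerance of 1e−8.  Three safeguards matter in practice:
Hessian eigenvalues are floored at max(1e−6, 1% of the largest eigenvalue)
— far from the mode the criterion is non-convex and a naive
positive-definite shift produces near-singular systems with absurd steps;
Newton steps are capped at norm 4 (conditional modes live within a few BSV
standard deviations of zero); and steps shorter than 1e−5 are taken without
a line search, because so close to the mode the objective decrease is below
line-search resolution while pure Newton is locally contractive.  Subjects
that still fail restart from η = 0; a subject whose gradient ends below
1e−5 is treated as converged (the induced OFV error is ~grad²/curvature,
far below any tolerance used downstream).

*Outer problem*: L-BFGS-B over the logs of
(θ_CL, θ_V, ω²_CL, ω²_V, σ²_prop, σ²_add) — positivity for free, roughly
scale-free steps — warm-starting the conditional modes between objective
evaluations, followed by a short Nelder-Mead polish (the objective carries
~1e−9 relative noise from the inner solves).  Starting values default to a
naive two-stage initializer: per-subject log-linear regression of
concentration on time pooled into geometric-mean typical values and
log-scale variances.  Refits inside the resampling drivers start from the
base fit's estimates, skip the polish, and use tightened parameter bounds
(±4 log units around the base estimates): deleting or resampling subjects
never moves an optimum that far, and the tight box keeps the line search
out of degenerate-variance regions where inner solves are expensive.
A fit that throws or returns a non-finite objective is recorded with
status `failed` and never raises: resampling drivers must survive failed
refits, which are simply missing columns downstream.

## Synthetic studies

The generator emulates a dense single-dose design: by default 100 subjects,
one IV bolus (dose 100, arbitrary units — no dose is implied by the design
itself) at t = 0, sampling at 0, 0.25, 0.5, 0.75, 1, 1.5, 2, 2.5, 3, 4, 6,
8, 12, 16, 20, 24 h.  The t = 0 record appears twice: once as the dose
record (MDV = 1) and once as an observation — an IV bolus makes C(0) = D/V
well-defined.  Negative simulated concentrations (possible under additive
error) are truncated to 0 and kept as observations.  Body weight is drawn
from a two-component normal mixture, N(50, 7.5²) with probability 0.85 and
N(95, 7.5²) otherwise — a typical cohort with an overweight subgroup; WT
enters no structural equation and exists purely for covariate-distribution
diagnostics.

Default generating parameters are θ_CL = 0.35 (volume/time),
θ_V = 2.0 (volume), ω² = 0.09 on both (≈30% CV), σ²_prop = 0.01 (10%
proportional CV), σ²_add = 0.04 (additive SD 0.2 against C(0) = 50).  They
were chosen once as a realistic dense-sampling scenario: elimination
half-life ln 2·V/CL ≈ 4 h, so the 24 h window spans about six half-lives
and every sample carries information.  What the generator does *not*
emulate: covariate–parameter relationships, dropout/missingness, LLOQ
censoring, multiple dosing, and η correlation.  Tests passing on these
data therefore demonstrate correctness of the machinery under the assumed
model, not robustness to the misspecification real datasets bring.

One consequence of the truncation rule is worth stating plainly: at the
defaults, about 1% of observations — late samples of fast-eliminating
subjects, whose predicted concentration falls below the additive noise
floor — are clipped at zero.  Clipping shrinks the observed residual
spread, so σ²_add estimates sit systematically ~20% low on such data; this
is a property of the data-generating rule, not of the estimator (the bias
vanishes when truncation is disabled).  The parameter-recovery test
therefore uses a slow-elimination truth (θ_V = 8, half-life ≈ 16 h over
the 24 h window) under which no observation truncates and the assumed
error model holds exactly; the defaults are kept for the resampling
diagnostics, where mild truncation is realistic.

## Resampling drivers

Case deletion produces one run per subject; deletion order is sequential
except every 10th run (configurable) draws its target uniformly from the
not-yet-deleted pool, reproducing the "perturb pool" pattern by a
documented, seeded rule.  The bootstrap resamples subjects with
replacement, preserving cohort size.  Bootstrap duplicates are relabeled as
distinct subjects for fitting (the standard case bootstrap) and their EBEs
averaged back onto the original subject ID, since the diagnostic matrix is
indexed by original subject.  A matrix entry is missing exactly when the
subject was absent from the run or the run failed.

## Diagnostics

* **Per-run scaling**: each column is mapped by (x − min)/(max − min), so
  every non-constant run attains 0 and 1 exactly and all runs share unit
  axis length.  The procedure is stated per run but the bounds are also
  described as global extremes; this package normalizes per run (the
  procedure as stated) and offers a `global_scale` flag, default off.
  Constant columns map to 0.5 — no order information exists in them.
* **Classical (Torgerson) MDS**: runs are dimensions, subjects are points;
  B = −½·J·D²·J is eigendecomposed, the top-k eigenvectors scaled by
  √eigenvalue.  Missing entries are imputed with the subject's row mean
  first (minimal-assumption; under subject-deletion there is exactly one
  structural hole per column).  Negative eigenvalues — possible after
  imputation — are clamped to zero; each axis's sign is fixed by making its
  largest-magnitude coordinate positive, so embeddings are deterministic
  across platforms.  MDS points are labeled by subject ID; under
  single-subject deletion the deletion-run index coincides with the deleted
  subject, so either reading of the labels is consistent.
* **Influence flags**: a run is influential when its population estimate
  falls outside the empirical [5, 95] percentile interval (bounds
  configurable) of all successful runs' estimates — the resampling
  distribution's own percentile envelope.  By construction roughly 10% of
  well-behaved runs land outside their own 5–95 envelope, so flags are
  screening candidates ranked by extremity, not hypothesis tests.  Fewer
  than 20 successful runs triggers an instability warning; fewer than 2 is
  an error.
* **Design checks**: deletion sequences are reported with a strict
  sequentiality flag; bootstrap inclusion counts are tested against
  uniformity with a chi-square goodness-of-fit on per-subject totals.
* **Distribution checks**: each run's values (covariate or EBE) are
  compared with the original cohort by a two-sample Kolmogorov–Smirnov
  test — the "formal test for equality of distributions", which is
  otherwise unnamed — with Benjamini–Hochberg adjustment across runs, plus
  Gaussian KDE summaries (Silverman bandwidth) for density overlays.

## Linked rendering

Interactive brushing is emulated statically: a `SelectionState` maps
subject IDs to colors and is applied identically to every panel (parallel
coordinates, concentration–time profiles, MDS scatter, variance plot); each
renderer also emits a JSON manifest naming the elements drawn per subject,
which is the machine-checkable surface of "linking".  Parallel axes are
horizontal and stacked (values connected downwards), with a flag for the
conventional vertical layout.  Default colors come from a fixed palette
keyed by a hash of the subject ID, so colors are stable across runs and
processes.

## Problem sizes

The test suite exercises full 100-subject fits (parameter recovery across
10 seeds) but runs the complete pipeline at 20 subjects with 10 bootstrap
replicates, and the injected-outlier study (50 subjects, one subject at 5×
typical clearance, 20 replications) at 8 of the 16 design times — sizes
chosen so the whole suite stays desk-scale while every contract is
exercised at the stated dimensions.  The acceptance script runs the
resampling chain at the full printed scale (100 subjects × 16 samples, 100
deletion refits, 50 bootstrap replicates).

## Known limitations

Single compartment, single bolus dose, no covariate submodels, no
NONMEM/PsN interoperability, no standard errors from an information matrix
(uncertainty comes from the bootstrap), no stratified bootstrap, and no
live GUI.  Exact NONMEM numerics are not reproduced; the FOCE-I objective
here is a self-contained Laplace implementation validated against
quadrature and closed forms instead.
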