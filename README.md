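# pkresample

Resampling diagnostics for population pharmacokinetic (PopPK) models:
simulate a dense single-dose study, fit a one-compartment nonlinear
mixed-effects model, rerun the fit under case deletion and the case
bootstrap, and find influential subjects by visualizing the resulting
subjects-by-runs estimate matrices with parallel coordinates and classical
multidimensional scaling (MDS), linked by subject ID.

It is aimed at pharmacometricians and biostatisticians who want
model-validation diagnostics — "which subjects drive my parameter
estimates?" — as reproducible, scriptable artifacts rather than one-off
interactive sessions.

## Model

Concentrations follow a one-compartment IV-bolus model with exponential
between-subject variability and a combined residual-error model:

    C_ij = (Dose / V_i) · exp(−(CL_i / V_i) · t_ij)
    CL_i = θ_CL · exp(η_CL,i),   V_i = θ_V · exp(η_V,i),   η ~ N(0, Ω)
    y_ij = C_ij · (1 + ε_prop,ij) + ε_add,ij

with Ω = diag(ω²_CL, ω²_V) and residual variances (σ²_prop, σ²_add).
Estimation is a Laplace approximation at the per-subject conditional modes
with interaction (the standard reading of FOCE-I); the elimination rate
constant Ke_i = CL_i / V_i is derived, never stored.

The resampling drivers refit this model once per perturbed dataset:

* **case deletion (cdd)** — every subject removed in exactly one run
  (mostly sequential, periodically broken by a seeded "perturb" draw), a
  run's estimate landing outside the empirical 5–95 percentile envelope of
  all runs flagging the deleted subject as influential;
* **case bootstrap** — subjects resampled with replacement, size preserved,
  quantifying estimate uncertainty.

Each run contributes one column to a subjects × runs matrix of
EBE-derived individual estimates (CL, V, Ke), with an explicit missing
marker where a subject was absent from a run.  Each run (column) is then
min–max scaled to unit length for parallel-coordinate display, and the
matrix is embedded in 2-D by classical (Torgerson) MDS — rows are subjects,
runs are dimensions — so influential subjects separate from the cloud.

## Worked example

```python
from pkresample import (PopParams, StudyDesign, simulate_dataset, fit,
                        cdd_design, run_resampling, influence_flags,
                        classical_mds, normalize_runs)
import numpy as np

pop = PopParams()                       # θ_CL=0.35, θ_V=2.0, ω²=0.09, ...
design = StudyDesign(n_subjects=20)     # 16 samples over 24 h, IV bolus
data = simulate_dataset(design, pop, seed=7)

base = fit(data)
print(base.status, round(base.ofv, 2))
print(round(base.pop_hat.theta_cl, 4), round(base.pop_hat.theta_v, 4))

cdd = cdd_design(data.subject_ids, perturb_period=10, seed=7)
fits, mats = run_resampling(data, cdd, init=base.pop_hat)
report = influence_flags({"CL": mats["CL"].pop_estimates}, cdd)
print(report.flagged_subjects("CL"))

emb = classical_mds(mats["CL"])
norms = np.linalg.norm(emb.points, axis=1)
print(emb.labels[int(norms.argmax())])
```

prints

```
converged 1505.92
0.3208 1.7563
[8, 19]
8
```

The base fit converges with an objective (−2 log-likelihood) of 1505.92 and
typical values near the generating ones (θ_CL = 0.35, θ_V = 2.0; at n = 20
the sampling error is visible).  Deleting subject 8 or 19 moves the
population clearance estimate outside the 5–95 percentile envelope of all
20 deletion runs, and subject 8 also sits farthest from the origin in the
MDS embedding of the CL matrix — the two views agree on who is most
influential.  (A 5–95 envelope excludes roughly 10% of well-behaved runs by
construction; flags mark candidates for inspection, not verdicts.)

The same chain is available from the shell:

```bash
pkresample simulate --n-subjects 100 --seed 1 --out data.csv
pkresample fit data.csv --out fit.json
pkresample cdd data.csv --perturb-period 10 --seed 1 --out cdd_out/
pkresample diagnose cdd_out/ --param CL --out report/
pkresample plot parallel cdd_out/ --select 20,52 --out fig/pc.png
pkresample pipeline --n-subjects 20 --reps 10 --out full_run/
```

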