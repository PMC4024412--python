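"""Case-deletion and bootstrap resampling drivers.

Each driver builds a :class:`RunDesign` (which subjects are in or out of
each run), materializes the perturbed dataset, refits the population model,
and assembles one subjects-by-runs :class:`ResampleMatrix` per parameter
(CL, V, Ke) of EBE-derived individual estimates, with an explicit missing
marker wherever a subject was absent from a run (or the run failed) — the
multivariate table the downstream parallel-coordinate and MDS diagnostics
consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimate import FitResult, FOCEFitter
from .pkmodel import PopParams
from .simulate import PKDataset

__all__ = [
    "RunDesign",
    "ResampleMatrix",
    "cdd_design",
    "bootstrap_design",
    "cdd_group_design",
    "cdd_observation_design",
    "run_resampling",
]

logger = logging.getLogger(__name__)

PARAMETERS = ("CL", "V", "Ke")


@dataclass(frozen=True)
class Run:
    run_id: str
    included: tuple  # subject ids, with repeats for bootstrap
    excluded: tuple
    # for observation deletion: (subject_id, row position within subject)
    deleted_obs: tuple | None = None

    def multiplicity(self, sid) -> int:
        return sum(1 for s in self.included if s == sid)


@dataclass(frozen=True)
class RunDesign:
    """Per-run record of which subjects were included or excluded."""

    runs: tuple
    kind: str  # cdd_subject | cdd_group | cdd_observation | bootstrap
    seed: int | None = None
    subject_ids: tuple = ()

    def __post_init__(self):
        if self.kind not in ("cdd_subject", "cdd_group", "cdd_observation",
                             "bootstrap"):
            raise ValueError(f"unknown design kind {self.kind!r}")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def deletion_order(self) -> list:
        """For cdd designs: the deleted subject(s) of each run, flattened."""
        return [sid for run in self.runs for sid in run.excluded]

    def inclusion_counts(self) -> pd.DataFrame:
        """Runs x subjects table of inclusion multiplicities."""
        pos = {sid: i for i, sid in enumerate(self.subject_ids)}
        counts = np.zeros((len(self.runs), len(pos)), dtype=int)
        for r, run in enumerate(self.runs):
            idx = np.fromiter((pos[s] for s in run.included), dtype=int,
                              count=len(run.included))
            counts[r] = np.bincount(idx, minlength=len(pos))
        return pd.DataFrame(counts, index=[r.run_id for r in self.runs],
                            columns=list(self.subject_ids))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for run in self.runs:
            rows.append(
                {
                    "run_id": run.run_id,
                    "excluded": ";".join(str(s) for s in run.excluded),
                    "included": ";".join(str(s) for s in run.included),
                }
            )
        return pd.DataFrame(rows)


def cdd_design(subject_ids, perturb_period: int = 10, seed: int = 0) -> RunDesign:
    """Case-deletion design: every subject deleted in exactly one run.

    Deletion is sequential except that every ``perturb_period``-th run draws
    its deletion target uniformly (seeded) from the not-yet-deleted pool;
    ``perturb_period = 0`` is strictly sequential.
    """
    subject_ids = list(subject_ids)
    if len(subject_ids) < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    pool = list(subject_ids)
    order = []
    for r in range(1, len(subject_ids) + 1):
        if perturb_period > 0 and r % perturb_period == 0 and len(pool) > 1:
            pick = pool[int(rng.integers(len(pool)))]
        else:
            pick = pool[0]
        pool.remove(pick)
        order.append(pick)
    runs = tuple(
        Run(
            run_id=f"cdd_{r + 1:04d}",
            included=tuple(s for s in subject_ids if s != sid),
            excluded=(sid,),
        )
        for r, sid in enumerate(order)
    )
    return RunDesign(runs=runs, kind="cdd_subject", seed=seed,
                     subject_ids=tuple(subject_ids))


def bootstrap_design(subject_ids, n_reps: int = 50, seed: int = 0) -> RunDesign:
    """Case bootstrap: each run resamples all subjects with replacement."""
    subject_ids = list(subject_ids)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(subject_ids)
    runs = []
    for r in range(n_reps):
        draw = rng.integers(0, n, size=n)
        included = tuple(subject_ids[i] for i in sorted(draw))
        excluded = tuple(s for s in subject_ids if s not in set(included))
        runs.append(
            Run(run_id=f"boot_{r + 1:04d}", included=included, excluded=excluded)
        )
    return RunDesign(runs=tuple(runs), kind="bootstrap", seed=seed,
                     subject_ids=tuple(subject_ids))


def cdd_group_design(subject_ids, group_size: int, seed: int = 0) -> RunDesign:
    """Delete disjoint blocks of ``group_size`` subjects per run (the last
    block takes any remainder)."""
    subject_ids = list(subject_ids)
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size >= len(subject_ids):
        raise ValueError("group_size must be smaller than the subject count")
    if group_size == 1:
        return cdd_design(subject_ids, perturb_period=0, seed=seed)
    runs = []
    r = 0
    for start in range(0, len(subject_ids), group_size):
        block = subject_ids[start:start + group_size]
        if not block:
            break
        r += 1
        runs.append(
            Run(
                run_id=f"cddg_{r:04d}",
                included=tuple(s for s in subject_ids if s not in set(block)),
                excluded=tuple(block),
            )
        )
    return RunDesign(runs=tuple(runs), kind="cdd_group", seed=seed,
                     subject_ids=tuple(subject_ids))


def cdd_observation_design(data: PKDataset, seed: int = 0) -> RunDesign:
    """One run per observation record; that single record is deleted."""
    subject_ids = data.subject_ids
    runs = []
    r = 0
    for sid in subject_ids:
        n_obs = int((data.df["ID"].eq(sid) & data.df["MDV"].eq(0)).sum())
        for j in range(n_obs):
            r += 1
            runs.append(
                Run(
                    run_id=f"cddo_{r:04d}",
                    included=tuple(subject_ids),
                    excluded=(),
                    deleted_obs=(sid, j),
                )
            )
    return RunDesign(runs=tuple(runs), kind="cdd_observation", seed=seed,
                     subject_ids=tuple(subject_ids))


@dataclass
class ResampleMatrix:
    """Subjects x runs grid of individual parameter estimates (Fig.-1-style).

    Entry (i, r) is NaN iff subject i was absent from run r or run r failed.
    ``pop_estimates`` holds each run's population-level estimate of the same
    parameter (used by the influence criterion); ``run_status`` each run's
    fit status.
    """

    parameter_name: str
    values: np.ndarray  # (n_subjects, n_runs), NaN = missing
    subject_ids: list
    run_labels: list
    pop_estimates: np.ndarray  # (n_runs,), NaN for failed runs
    run_status: list

    def __post_init__(self):
        if self.parameter_name not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter_name!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.run_labels)):
            raise ValueError("values shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.run_labels
        )

    def to_csv(self, path) -> str:
        df = self.to_frame()
        df.index.name = "ID"
        df.to_csv(path, na_rep="NA")
        return str(path)

    @classmethod
    def from_csv(cls, path, parameter_name="CL", pop_estimates=None,
                 run_status=None) -> "ResampleMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        n_runs = df.shape[1]
        return cls(
            parameter_name=parameter_name,
            values=df.to_numpy(dtype=float),
            subject_ids=list(df.index),
            run_labels=list(df.columns),
            pop_estimates=(np.full(n_runs, np.nan) if pop_estimates is None
                           else np.asarray(pop_estimates, dtype=float)),
            run_status=run_status or ["converged"] * n_runs,
        )


def _materialize(data: PKDataset, run: Run) -> tuple[PKDataset, dict]:
    """Build the perturbed dataset for one run.

    Returns (dataset, origin map new_id -> original_id).  Bootstrap
    duplicates are relabeled as fresh subjects so the fit treats them as
    independent cases.
    """
    if run.deleted_obs is not None:
        sid, j = run.deleted_obs
        df = data.df.copy()
        obs_idx = df.index[(df["ID"] == sid) & (df["MDV"] == 0)]
        df = df.drop(obs_idx[j])
        return PKDataset(df, validate=False), {s: s for s in data.subject_ids}

    counts: dict = {}
    for sid in run.included:
        counts[sid] = counts.get(sid, 0) + 1
    if all(c == 1 for c in counts.values()):
        sub = data.subset(list(counts))
        return sub, {s: s for s in sub.subject_ids}

    pieces, origin = [], {}
    new_id = 0
    for sid in data.subject_ids:
        for _copy in range(counts.get(sid, 0)):
            new_id += 1
            block = data.df[data.df["ID"] == sid].copy()
            block["ID"] = new_id
            pieces.append(block)
            origin[new_id] = sid
    return PKDataset(pd.concat(pieces, ignore_index=True), validate=False), origin


def run_resampling(
    data: PKDataset,
    design: RunDesign,
    fit_options: dict | None = None,
    init: PopParams | None = None,
    progress: bool = False,
) -> tuple[list, dict]:
    """Refit the model on every run of a design.

    Returns (fit results in run order, {parameter -> ResampleMatrix}).
    For a subject sampled multiple times in a bootstrap run the matrix entry
    is the mean of its copies' EBE values; a failed run leaves its whole
    column missing.  Raises only if every run failed.
    """
    fit_options = dict(fit_options or {})
    if init is not None:
        # refits start from the base estimates; the L-BFGS-B stage alone
        # re-converges, so the polish stage is off and the outer tolerance
        # relaxed (still ~1e-6 absolute on the OFV) unless requested
        fit_options.setdefault("polish", False)
        fit_options.setdefault("outer_ftol", 1e-9)
        # a perturbed-cohort optimum sits near the base optimum; tight
        # bounds keep the line search out of degenerate-variance regions
        fit_options.setdefault("log_bound_range", (4.0, 4.0))
    subject_ids = data.subject_ids
    unknown = [s for run in design.runs for s in run.included
               if s not in set(subject_ids)]
    if unknown:
        raise KeyError(f"design references unknown subjects: {sorted(set(unknown))}")
    n, n_runs = len(subject_ids), design.n_runs
    index = {sid: i for i, sid in enumerate(subject_ids)}
    grids = {p: np.full((n, n_runs), np.nan) for p in PARAMETERS}
    pop_est = {p: np.full(n_runs, np.nan) for p in PARAMETERS}
    statuses, results = [], []

    for r, run in enumerate(design.runs):
        sub, origin = _materialize(data, run)
        fitter = FOCEFitter(init=init, run_label=run.run_id, **fit_options)
        res = fitter.fit(sub).result_
        results.append(res)
        statuses.append(res.status)
        if progress:
            logger.info("run %s: status=%s ofv=%.3f", run.run_id, res.status,
                        res.ofv)
        if not res.usable or res.pop_hat is None:
            continue
        pop_est["CL"][r] = res.pop_hat.theta_cl
        pop_est["V"][r] = res.pop_hat.theta_v
        pop_est["Ke"][r] = res.pop_hat.theta_cl / res.pop_hat.theta_v
        acc: dict = {}
        for new_id, p in res.ebes.items():
            osid = origin[new_id]
            acc.setdefault(osid, []).append((p.cl, p.v, p.ke))
        for osid, vals in acc.items():
            i = index[osid]
            arr = np.asarray(vals)
            grids["CL"][i, r] = arr[:, 0].mean()
            grids["V"][i, r] = arr[:, 1].mean()
            grids["Ke"][i, r] = arr[:, 2].mean()

    if all(s == "failed" for s in statuses):
        raise RuntimeError("every resampling run failed to fit")

    run_labels = [run.run_id for run in design.runs]
    matrices = {
        p: ResampleMatrix(
            parameter_name=p,
            values=grids[p],
            subject_ids=list(subject_ids),
            run_labels=run_labels,
            pop_estimates=pop_est[p],
            run_status=list(statuses),
        )
        for p in PARAMETERS
    }
    return results, matrices
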