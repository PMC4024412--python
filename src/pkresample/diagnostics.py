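"""Diagnostic statistics for resampling matrices.

* per-run min-max scaling so every case-deletion run spans the same unit
  axis in a parallel-coordinate plot;
* classical (Torgerson) multidimensional scaling of the subjects-by-runs
  matrix, each run treated as one dimension;
* influence flags from the empirical percentile envelope of the runs'
  population estimates;
* design-validation summaries (deletion order, bootstrap inclusion
  uniformity) and per-run equality-of-distribution tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .resample import ResampleMatrix, RunDesign

__all__ = [
    "ScaledMatrix",
    "MDSEmbedding",
    "InfluenceReport",
    "RunScaler",
    "ClassicalMDS",
    "normalize_runs",
    "classical_mds",
    "influence_flags",
    "ebe_variance",
    "design_check",
    "distribution_check",
]


# ---------------------------------------------------------------------------
# per-run scaling


@dataclass
class ScaledMatrix:
    """Subjects x runs values scaled to [0, 1] per run (column)."""

    values: np.ndarray
    subject_ids: list
    run_labels: list
    col_min: np.ndarray  # original-scale per-run minima (axis annotation)
    col_max: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.run_labels)


class RunScaler(BaseEstimator, TransformerMixin):
    """Column-wise min-max scaler tolerant of missing entries.

    Each column (resampling run) is mapped onto [0, 1] by
    (x - min) / (max - min) so that every run spans the same unit length;
    NaNs are preserved and constant columns map to 0.5.  With
    ``global_scale=True`` a single min/max over the whole matrix is used
    instead (alternative reading of "global maximum/minimum").
    """

    def __init__(self, global_scale: bool = False):
        self.global_scale = global_scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty matrix")
        if np.all(np.isnan(X)):
            raise ValueError("matrix has no non-missing entries")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if self.global_scale:
                lo = np.full(X.shape[1], np.nanmin(X))
                hi = np.full(X.shape[1], np.nanmax(X))
            else:
                lo = np.nanmin(X, axis=0)
                hi = np.nanmax(X, axis=0)
        self.data_min_ = lo
        self.data_max_ = hi
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        lo, hi = self.data_min_, self.data_max_
        span = hi - lo
        out = np.empty_like(X)
        const = ~(span > 0)
        nz = ~const
        out[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
        out[:, const] = np.where(np.isnan(X[:, const]), np.nan, 0.5)
        return out


def normalize_runs(m: ResampleMatrix, global_scale: bool = False) -> ScaledMatrix:
    """Scale each run of a resampling matrix onto the unit interval."""
    X = m.values
    if X.size == 0:
        raise ValueError("empty resampling matrix")
    if np.any(np.all(np.isnan(X), axis=0)):
        bad = [m.run_labels[j] for j in np.where(np.all(np.isnan(X), axis=0))[0]]
        raise ValueError(f"runs with no non-missing entries: {bad}")
    scaler = RunScaler(global_scale=global_scale).fit(X)
    return ScaledMatrix(
        values=scaler.transform(X),
        subject_ids=list(m.subject_ids),
        run_labels=list(m.run_labels),
        col_min=scaler.data_min_.copy(),
        col_max=scaler.data_max_.copy(),
    )


# ---------------------------------------------------------------------------
# classical (Torgerson) MDS


@dataclass
class MDSEmbedding:
    """Low-dimensional configuration from classical scaling."""

    points: np.ndarray  # (n, k), centered
    eigenvalues: np.ndarray  # full ordered spectrum of the centered matrix
    labels: list

    @property
    def explained_fraction(self) -> np.ndarray:
        """Fraction of the (clamped) eigenvalue sum carried by each retained
        axis."""
        lam = np.maximum(self.eigenvalues, 0.0)
        total = lam.sum()
        k = self.points.shape[1]
        if total <= 0:
            return np.zeros(k)
        return lam[:k] / total


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Classical (Torgerson) multidimensional scaling.

    Pairwise Euclidean distances D between rows are double-centered,
    B = -1/2 * J D^2 J, and the embedding is the top-``n_components``
    eigenvectors of B scaled by the square roots of their (non-negative,
    clamped) eigenvalues.  Exact for genuinely Euclidean configurations.
    Missing entries are imputed with the row mean before computing
    distances.  Signs are fixed by making each axis's largest-magnitude
    coordinate positive.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 rows")
        if self.n_components > n - 1:
            raise ValueError("n_components must be <= n_rows - 1")
        all_missing = np.where(np.all(np.isnan(X), axis=1))[0]
        if all_missing.size:
            raise ValueError(f"rows with no non-missing entries: "
                             f"{all_missing.tolist()}")
        if np.any(np.isnan(X)):
            row_mean = np.nanmean(X, axis=1)
            X = np.where(np.isnan(X), row_mean[:, None], X)
        d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        b = 0.5 * (b + b.T)
        lam, vec = np.linalg.eigh(b)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        self.eigenvalues_ = lam.copy()
        k = self.n_components
        lam_k = np.maximum(lam[:k], 0.0)
        pts = vec[:, :k] * np.sqrt(lam_k)[None, :]
        for c in range(k):
            i = np.argmax(np.abs(pts[:, c]))
            if pts[i, c] < 0:
                pts[:, c] = -pts[:, c]
        self.embedding_ = pts - pts.mean(axis=0, keepdims=True)
        return self.embedding_

    def transform(self, X):
        # classical scaling has no out-of-sample map; transform refits
        return self.fit_transform(X)


def classical_mds(m: ResampleMatrix | np.ndarray, k: int = 2,
                  labels=None) -> MDSEmbedding:
    """Torgerson MDS of a resampling matrix (rows = subjects, dims = runs)."""
    if isinstance(m, ResampleMatrix):
        X = m.values
        labels = list(m.subject_ids)
    else:
        X = np.asarray(m, dtype=float)
        labels = list(labels) if labels is not None else list(range(X.shape[0]))
    est = ClassicalMDS(n_components=k)
    pts = est.fit_transform(X)
    return MDSEmbedding(points=pts, eigenvalues=est.eigenvalues_, labels=labels)


# ---------------------------------------------------------------------------
# influence flags


@dataclass
class InfluenceReport:
    """Per-run influence flags against a percentile envelope."""

    table: pd.DataFrame  # parameter, run_id, deleted_subject, pop_estimate,
    #                      lower_bound, upper_bound, flagged
    lower: float
    upper: float

    def flagged_runs(self, parameter=None) -> pd.DataFrame:
        t = self.table[self.table["flagged"]]
        if parameter is not None:
            t = t[t["parameter"] == parameter]
        return t

    def flagged_subjects(self, parameter=None) -> list:
        t = self.flagged_runs(parameter)
        return sorted(
            {s for s in t["deleted_subject"] if s is not None and s == s}
        )


def influence_flags(
    pop_estimates_per_run: dict,
    design: RunDesign,
    lower: float = 5.0,
    upper: float = 95.0,
) -> InfluenceReport:
    """Flag runs whose population estimate leaves the percentile envelope.

    ``pop_estimates_per_run`` maps parameter name -> array of per-run
    population estimates (NaN for failed runs).  A run is flagged when its
    estimate falls strictly outside the empirical [lower, upper] percentile
    interval of all successful runs' estimates for that parameter.  For
    case-deletion runs the flag names the deleted subject.
    """
    if not 0 <= lower < upper <= 100:
        raise ValueError("need 0 <= lower < upper <= 100")
    rows = []
    for param, est in pop_estimates_per_run.items():
        est = np.asarray(est, dtype=float)
        if est.size != design.n_runs:
            raise ValueError(f"{param}: {est.size} estimates for "
                             f"{design.n_runs} runs")
        ok = np.isfinite(est)
        n_ok = int(ok.sum())
        if n_ok < 2:
            raise ValueError(f"{param}: fewer than 2 successful runs")
        if n_ok < 20:
            warnings.warn(
                f"{param}: only {n_ok} successful runs; percentile bounds "
                "are unstable", stacklevel=2,
            )
        lo = float(np.percentile(est[ok], lower))
        hi = float(np.percentile(est[ok], upper))
        for r, run in enumerate(design.runs):
            deleted = run.excluded[0] if len(run.excluded) == 1 else (
                None if not run.excluded else run.excluded)
            value = est[r]
            flagged = bool(np.isfinite(value) and (value < lo or value > hi))
            rows.append(
                {
                    "parameter": param,
                    "run_id": run.run_id,
                    "deleted_subject": deleted
                    if design.kind.startswith("cdd") else None,
                    "pop_estimate": value,
                    "lower_bound": lo,
                    "upper_bound": hi,
                    "flagged": flagged,
                }
            )
    return InfluenceReport(table=pd.DataFrame(rows), lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# EBE variance across runs


def ebe_variance(m: ResampleMatrix) -> pd.DataFrame:
    """Per-subject sample variance (ddof=1) of estimates across runs.

    Returned sorted descending; subjects present in fewer than two runs get
    a missing variance and a warning.
    """
    counts = np.sum(~np.isnan(m.values), axis=1)
    out = np.full(len(m.subject_ids), np.nan)
    for i in range(len(m.subject_ids)):
        if counts[i] >= 2:
            row = m.values[i]
            out[i] = float(np.nanvar(row, ddof=1))
    thin = [m.subject_ids[i] for i in np.where(counts < 2)[0]]
    if thin:
        warnings.warn(f"subjects present in < 2 runs: {thin}", stacklevel=2)
    df = pd.DataFrame(
        {"ID": m.subject_ids, "n_runs": counts, "variance": out}
    )
    return df.sort_values("variance", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# design validation


def design_check(design: RunDesign) -> dict:
    """Summaries validating a resampling design.

    cdd: the (run, deleted subject) sequence and whether it is strictly
    sequential.  bootstrap: the run x subject inclusion-count table plus a
    chi-square goodness-of-fit of per-subject total inclusion counts against
    the uniform expectation.
    """
    if design.kind.startswith("cdd"):
        order = design.deletion_order()
        seq = list(design.subject_ids)
        return {
            "kind": design.kind,
            "deletions": pd.DataFrame(
                {
                    "run_id": [r.run_id for r in design.runs
                               for _ in r.excluded],
                    "deleted_subject": order,
                }
            ),
            "is_strictly_sequential": order == seq[: len(order)],
        }
    table = design.inclusion_counts()
    totals = table.sum(axis=0).to_numpy(dtype=float)
    expected = totals.sum() / len(totals)
    chi2, p = stats.chisquare(totals, f_exp=np.full_like(totals, expected))
    return {
        "kind": design.kind,
        "inclusion_counts": table,
        "chi2": float(chi2),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# per-run distribution checks


def distribution_check(samples: dict, reference, gridsize: int = 128) -> dict:
    """Two-sample KS test of each run's values against a reference.

    ``samples`` maps run label -> 1-d values (e.g. WT of included subjects,
    or a run's CL EBEs); ``reference`` is the original dataset's values.
    P-values are Benjamini-Hochberg adjusted across runs.  Also returns a
    Silverman-bandwidth Gaussian KDE summary per run for density plots.
    """
    reference = np.asarray(reference, dtype=float)
    reference = reference[np.isfinite(reference)]
    if reference.size == 0:
        raise ValueError("reference is empty")
    rows, kept, densities = [], [], {}
    lo, hi = reference.min(), reference.max()
    for label, vals in samples.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            warnings.warn(f"run {label}: fewer than 2 values, skipped",
                          stacklevel=2)
            continue
        ks = stats.ks_2samp(vals, reference, method="auto")
        rows.append({"run": label, "ks_statistic": float(ks.statistic),
                     "p_value": float(ks.pvalue)})
        kept.append(label)
        lo = min(lo, vals.min())
        hi = max(hi, vals.max())
        densities[label] = vals
    if not rows:
        raise ValueError("no run had enough values to test")
    table = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(table["p_value"], method="fdr_bh")
    table["p_adjusted"] = p_adj

    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, gridsize)
    kde_out = {}
    for label, vals in densities.items():
        if np.ptp(vals) > 0:
            kde = stats.gaussian_kde(vals, bw_method="silverman")
            kde_out[label] = (grid, kde(grid))
        else:  # degenerate sample: a point mass has no density estimate
            kde_out[label] = (grid, np.full_like(grid, np.nan))
    ref_kde = stats.gaussian_kde(reference, bw_method="silverman") \
        if np.ptp(reference) > 0 else None
    return {
        "table": table,
        "densities": kde_out,
        "reference_density": (grid, ref_kde(grid)) if ref_kde else None,
    }
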