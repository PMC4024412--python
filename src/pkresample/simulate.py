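"""Synthetic study generator and NONMEM-style dataset IO.

The default study design mirrors a dense single-dose PopPK study: 100
subjects, one IV bolus at time 0, and plasma sampling at 0, 0.25, 0.5, 0.75,
1, 1.5, 2, 2.5, 3, 4, 6, 8, 12, 16, 20 and 24 h post-dose.  Body weight is
carried as a per-subject covariate drawn from a two-component normal mixture
(a main mode near 50 kg and an overweight mode near 95 kg); it enters no
structural equation and exists for covariate-distribution diagnostics.

Datasets are long-format tables with the NONMEM column convention
ID, TIME, DV, AMT, WT, MDV; missing DV is written as ".".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pkmodel import PopParams

__all__ = [
    "DEFAULT_SAMPLE_TIMES",
    "StudyDesign",
    "PKDataset",
    "simulate_dataset",
    "read_dataset",
    "write_dataset",
]

DEFAULT_SAMPLE_TIMES = (
    0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0,
    6.0, 8.0, 12.0, 16.0, 20.0, 24.0,
)

COLUMNS = ["ID", "TIME", "DV", "AMT", "WT", "MDV"]


@dataclass(frozen=True)
class WeightMixture:
    """Two-component normal mixture for body weight (kg)."""

    mean1: float = 50.0
    mean2: float = 95.0
    sd1: float = 7.5
    sd2: float = 7.5
    weight1: float = 0.85

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) < self.weight1
        wt = np.where(
            comp,
            rng.normal(self.mean1, self.sd1, n),
            rng.normal(self.mean2, self.sd2, n),
        )
        return np.clip(wt, 20.0, None)  # weights must stay positive


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the simulated study."""

    n_subjects: int = 100
    dose: float = 100.0
    sample_times: tuple = DEFAULT_SAMPLE_TIMES
    wt_mix: WeightMixture = field(default_factory=WeightMixture)

    def __post_init__(self) -> None:
        times = np.asarray(self.sample_times, dtype=float)
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if times.size == 0 or times[0] != 0:
            raise ValueError("sample_times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing")


class PKDataset:
    """Long-format PK dataset (one dose record + observations per subject).

    Thin wrapper around a pandas DataFrame with columns ID, TIME, DV, AMT,
    WT, MDV.  Dose records have AMT > 0, MDV = 1 and missing DV; observation
    records have AMT = 0 and MDV = 0.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.loc[:, COLUMNS].reset_index(drop=True)
        df = df.astype(
            {"ID": int, "TIME": float, "DV": float, "AMT": float,
             "WT": float, "MDV": int}
        )
        self.df = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        for sid, sub in df.groupby("ID", sort=False):
            doses = sub[(sub["AMT"] > 0) & (sub["MDV"] == 1)]
            if len(doses) != 1:
                raise ValueError(
                    f"subject {sid}: expected exactly one dose record, "
                    f"found {len(doses)}"
                )
            if (sub["MDV"] == 0).sum() < 1:
                raise ValueError(f"subject {sid}: no observation records")
            if np.any(np.diff(sub["TIME"].to_numpy()) < 0):
                raise ValueError(f"subject {sid}: times not non-decreasing")
            wt = sub["WT"].to_numpy()
            if not np.all(wt == wt[0]) or wt[0] <= 0:
                raise ValueError(f"subject {sid}: WT must be constant and > 0")

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"].tolist()))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def observations(self) -> pd.DataFrame:
        """Observation records only (MDV == 0)."""
        return self.df[self.df["MDV"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.df[(self.df["MDV"] == 1) & (self.df["AMT"] > 0)]

    def weights(self) -> pd.Series:
        """Per-subject body weight, indexed by subject ID."""
        return self.df.groupby("ID", sort=False)["WT"].first()

    def subset(self, subject_ids) -> "PKDataset":
        """Dataset restricted to the given subjects (all records kept)."""
        keep = set(subject_ids)
        missing = keep - set(self.subject_ids)
        if missing:
            raise KeyError(f"unknown subject ids: {sorted(missing)}")
        return PKDataset(self.df[self.df["ID"].isin(keep)], validate=False)

    def drop_subjects(self, subject_ids) -> "PKDataset":
        drop = set(subject_ids)
        return self.subset([s for s in self.subject_ids if s not in drop])

    def relabel(self, mapping: dict) -> "PKDataset":
        df = self.df.copy()
        df["ID"] = df["ID"].map(mapping)
        return PKDataset(df, validate=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKDataset):
            return NotImplemented
        a, b = self.df, other.df
        if a.shape != b.shape:
            return False
        for col in COLUMNS:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            if col == "DV":
                if not np.array_equal(np.isnan(x), np.isnan(y)):
                    return False
                m = ~np.isnan(x)
                if not np.array_equal(x[m], y[m]):
                    return False
            elif not np.array_equal(x, y):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"PKDataset({self.n_subjects} subjects, "
            f"{len(self.observations())} observations)"
        )


def simulate_dataset(
    design: StudyDesign,
    pop: PopParams,
    seed: int,
    eta_overrides: dict | None = None,
) -> PKDataset:
    """Simulate a dataset under the design and population model.

    Per subject: eta ~ N(0, diag(omega_cl2, omega_v2)) (optionally overridden
    via ``eta_overrides[subject_id] = (eta_cl, eta_v)``, used e.g. to inject
    a known outlier), WT from the weight mixture, and observations
    y = f*(1+eps_p) + eps_a at every design time.  Negative simulated
    concentrations are truncated to 0 and kept.  The record at t=0 is the
    dose record (MDV=1) plus a t=0 observation.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    times = np.asarray(design.sample_times, dtype=float)
    k = times.size

    eta_cl = rng.normal(0.0, np.sqrt(pop.omega_cl2), n)
    eta_v = rng.normal(0.0, np.sqrt(pop.omega_v2), n)
    wt = design.wt_mix.sample(n, rng)
    eps_p = rng.normal(0.0, np.sqrt(pop.sigma_prop2), (n, k))
    eps_a = rng.normal(0.0, np.sqrt(pop.sigma_add2), (n, k))

    ids = np.arange(1, n + 1)
    if eta_overrides:
        for sid, (ec, ev) in eta_overrides.items():
            idx = int(sid) - 1
            if not 0 <= idx < n:
                raise KeyError(f"eta_overrides: unknown subject id {sid}")
            eta_cl[idx], eta_v[idx] = ec, ev

    cl = pop.theta_cl * np.exp(eta_cl)
    v = pop.theta_v * np.exp(eta_v)
    f = (design.dose / v)[:, None] * np.exp(-(cl / v)[:, None] * times[None, :])
    y = np.maximum(f * (1.0 + eps_p) + eps_a, 0.0)

    rows = []
    for i in range(n):
        rows.append((ids[i], 0.0, np.nan, design.dose, wt[i], 1))
        for j in range(k):
            rows.append((ids[i], times[j], y[i, j], 0.0, wt[i], 0))
    df = pd.DataFrame(rows, columns=COLUMNS)
    return PKDataset(df)


def write_dataset(data: PKDataset, path) -> str:
    """Write a dataset as NONMEM-style CSV; missing DV encoded as "."."""
    df = data.df.copy()
    with open(path, "w") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            dv = "." if np.isnan(row.DV) else repr(float(row.DV))
            fh.write(
                f"{int(row.ID)},{row.TIME!r},{dv},{row.AMT!r},"
                f"{row.WT!r},{int(row.MDV)}\n"
            )
    return str(path)


def read_dataset(path) -> PKDataset:
    """Read a NONMEM-style CSV (header required; "." or empty = missing DV)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = [c.strip().upper() for c in header.split(",")]
        missing = [c for c in COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"{path}: line 1: missing required columns {missing}")
        idx = {c: cols.index(c) for c in COLUMNS}
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(cols):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, "
                    f"got {len(parts)}"
                )
            rec = []
            for col in COLUMNS:
                raw = parts[idx[col]].strip()
                if col == "DV" and raw in (".", ""):
                    rec.append(np.nan)
                    continue
                try:
                    rec.append(int(raw) if col in ("ID", "MDV") else float(raw))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric {col} value {raw!r}"
                    ) from exc
            rows.append(rec)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=COLUMNS)
    dup = df[(df["MDV"] == 1) & (df["AMT"] > 0)].duplicated(["ID", "TIME"])
    if dup.any():
        first = df[(df["MDV"] == 1) & (df["AMT"] > 0)][dup].index[0]
        raise ValueError(
            f"{path}: line {first + 2}: duplicate dose record for "
            f"subject {int(df.loc[first, 'ID'])}"
        )
    return PKDataset(df)
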