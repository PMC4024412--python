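"""Run configuration (YAML-serializable) and end-to-end pipeline driver."""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .pkmodel import PopParams
from .simulate import (
    DEFAULT_SAMPLE_TIMES,
    PKDataset,
    StudyDesign,
    WeightMixture,
    simulate_dataset,
    write_dataset,
)

logger = logging.getLogger("pkresample")

CONFIG_VERSION = 1


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage seed from the master seed and a run label."""
    return (int(master_seed) * 1000003 + zlib.crc32(label.encode())) % (2**31)


@dataclass
class RunConfig:
    """Defaults for the whole pipeline; every field overridable via CLI."""

    version: int = CONFIG_VERSION
    seed: int = 12345
    n_subjects: int = 100
    dose: float = 100.0
    sample_times: list = field(default_factory=lambda: list(DEFAULT_SAMPLE_TIMES))
    pop: dict = field(default_factory=lambda: PopParams().to_dict())
    wt_mix: dict = field(
        default_factory=lambda: {
            "mean1": 50.0, "mean2": 95.0, "sd1": 7.5, "sd2": 7.5,
            "weight1": 0.85,
        }
    )
    bootstrap_reps: int = 50
    perturb_period: int = 10
    percentile_lower: float = 5.0
    percentile_upper: float = 95.0

    def study_design(self) -> StudyDesign:
        return StudyDesign(
            n_subjects=self.n_subjects,
            dose=self.dose,
            sample_times=tuple(self.sample_times),
            wt_mix=WeightMixture(**self.wt_mix),
        )

    def pop_params(self) -> PopParams:
        return PopParams(**self.pop)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "RunConfig":
        if os.path.exists(str(text_or_path)):
            with open(text_or_path) as fh:
                payload = yaml.safe_load(fh)
        else:
            payload = yaml.safe_load(text_or_path)
        if not isinstance(payload, dict):
            raise ValueError("config must be a mapping")
        version = payload.get("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {version}")
        return cls(**payload)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """simulate -> fit -> cdd -> bootstrap -> diagnose -> plot.

    Writes every intermediate artifact under ``out_dir`` and returns a
    summary dict.  Idempotent given the seed.
    """
    from .diagnostics import (
        classical_mds,
        design_check,
        distribution_check,
        ebe_variance,
        influence_flags,
        normalize_runs,
    )
    from .estimate import fit
    from .resample import bootstrap_design, cdd_design, run_resampling
    from .viz import (
        SelectionState,
        design_plot,
        density_plot,
        linked_report,
        mds_plot,
        parallel_coordinate_plot,
        variance_plot,
    )

    os.makedirs(out_dir, exist_ok=True)
    summary: dict = {"stages": {}}

    # --- simulate ---------------------------------------------------------
    logger.info("stage simulate: n_subjects=%d", config.n_subjects)
    design = config.study_design()
    pop = config.pop_params()
    data = simulate_dataset(design, pop, derive_seed(config.seed, "simulate"))
    data_path = os.path.join(out_dir, "data.csv")
    write_dataset(data, data_path)
    summary["stages"]["simulate"] = {"n_subjects": data.n_subjects,
                                     "n_obs": int(len(data.observations()))}

    # --- base fit ---------------------------------------------------------
    logger.info("stage fit")
    base = fit(data, run_label="base")
    base.to_json(os.path.join(out_dir, "fit_base.json"))
    if base.status == "failed":
        raise RuntimeError("stage fit: base model fit failed")
    summary["stages"]["fit"] = {"status": base.status, "ofv": base.ofv}

    # --- cdd --------------------------------------------------------------
    logger.info("stage cdd: %d runs", data.n_subjects)
    cdd = cdd_design(data.subject_ids, perturb_period=config.perturb_period,
                     seed=derive_seed(config.seed, "cdd"))
    cdd_fits, cdd_mats = run_resampling(data, cdd, init=base.pop_hat)
    cdd_dir = os.path.join(out_dir, "cdd")
    _write_resampling(cdd_dir, cdd, cdd_fits, cdd_mats)
    n_failed = sum(1 for f in cdd_fits if f.status == "failed")
    summary["stages"]["cdd"] = {"n_runs": cdd.n_runs, "n_failed": n_failed}
    logger.info("stage cdd: %d/%d runs failed", n_failed, cdd.n_runs)

    # --- bootstrap --------------------------------------------------------
    logger.info("stage bootstrap: %d reps", config.bootstrap_reps)
    boot = bootstrap_design(data.subject_ids, n_reps=config.bootstrap_reps,
                            seed=derive_seed(config.seed, "bootstrap"))
    boot_fits, boot_mats = run_resampling(data, boot, init=base.pop_hat)
    boot_dir = os.path.join(out_dir, "bootstrap")
    _write_resampling(boot_dir, boot, boot_fits, boot_mats)
    nb_failed = sum(1 for f in boot_fits if f.status == "failed")
    summary["stages"]["bootstrap"] = {"n_runs": boot.n_runs,
                                      "n_failed": nb_failed}

    # --- diagnostics ------------------------------------------------------
    logger.info("stage diagnose")
    diag_dir = os.path.join(out_dir, "diagnostics")
    os.makedirs(diag_dir, exist_ok=True)
    cl = cdd_mats["CL"]
    scaled = normalize_runs(cl)
    scaled.to_frame().to_csv(os.path.join(diag_dir, "scaled_CL.csv"),
                             na_rep="NA")
    emb = classical_mds(cl)
    import pandas as pd

    pd.DataFrame(emb.points, index=emb.labels,
                 columns=["mds1", "mds2"]).to_csv(
        os.path.join(diag_dir, "mds_CL.csv"))
    report = influence_flags(
        {p: cdd_mats[p].pop_estimates for p in ("CL", "V", "Ke")},
        cdd,
        lower=config.percentile_lower,
        upper=config.percentile_upper,
    )
    report.table.to_csv(os.path.join(diag_dir, "influence.csv"), index=False)
    checks = design_check(boot)
    checks["inclusion_counts"].to_csv(
        os.path.join(diag_dir, "bootstrap_inclusion.csv"))
    wts = data.weights()
    wt_samples = {
        run.run_id: wts.loc[list(dict.fromkeys(run.included))].to_numpy()
        for run in cdd.runs
    }
    dist = distribution_check(wt_samples, wts.to_numpy())
    dist["table"].to_csv(os.path.join(diag_dir, "wt_ks.csv"), index=False)
    variances = ebe_variance(boot_mats["CL"])
    variances.to_csv(os.path.join(diag_dir, "cl_variance.csv"), index=False)
    flagged = report.flagged_subjects("CL")
    summary["stages"]["diagnose"] = {
        "flagged_subjects_CL": flagged,
        "bootstrap_chi2_p": checks["p_value"],
    }

    # --- plots ------------------------------------------------------------
    logger.info("stage plot")
    fig_dir = os.path.join(out_dir, "figures")
    os.makedirs(fig_dir, exist_ok=True)
    sel = SelectionState({sid: "red" for sid in flagged[:2]})
    parallel_coordinate_plot(scaled, sel,
                             os.path.join(fig_dir, "parallel_CL.png"))
    mds_plot(emb, sel, os.path.join(fig_dir, "mds_CL.png"))
    design_plot(cdd, os.path.join(fig_dir, "design_cdd.png"))
    design_plot(boot, os.path.join(fig_dir, "design_bootstrap.png"))
    density_plot(dist["densities"], os.path.join(fig_dir, "wt_density.png"),
                 reference=dist["reference_density"], xlabel="weight (kg)")
    variance_plot(variances, sel, os.path.join(fig_dir, "cl_variance.png"))
    linked_report(scaled, data, emb, sel, out_dir=fig_dir)

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


def _write_resampling(out_dir, design, fits, matrices):
    os.makedirs(out_dir, exist_ok=True)
    design.to_frame().to_csv(os.path.join(out_dir, "design.csv"), index=False)
    import pandas as pd

    pd.DataFrame(
        {"run_id": [r.run_id for r in design.runs],
         "status": [f.status for f in fits],
         "ofv": [f.ofv for f in fits]}
    ).to_csv(os.path.join(out_dir, "run_status.csv"), index=False)
    for p, m in matrices.items():
        m.to_csv(os.path.join(out_dir, f"matrix_{p}.csv"))
    fit_dir = os.path.join(out_dir, "fits")
    os.makedirs(fit_dir, exist_ok=True)
    for f in fits:
        f.to_json(os.path.join(fit_dir, f"{f.run_label}.json"))
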