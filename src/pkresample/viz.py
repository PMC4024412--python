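"""Static rendering of the resampling diagnostics with linked selection.

Interactive brushing is emulated by an explicit :class:`SelectionState`
(subject id -> color) applied identically to every panel, plus a
machine-readable JSON manifest listing, per panel, the graphical elements
mapped to each subject — the testable surface of "linking".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .diagnostics import MDSEmbedding, ScaledMatrix  # noqa: E402
from .resample import RunDesign  # noqa: E402
from .simulate import PKDataset  # noqa: E402

__all__ = [
    "SelectionState",
    "parallel_coordinate_plot",
    "mds_plot",
    "design_plot",
    "density_plot",
    "profile_plot",
    "variance_plot",
    "linked_report",
]

DEFAULT_COLOR = "0.65"
_PALETTE = plt.get_cmap("tab20").colors


def subject_color(subject_id) -> tuple:
    """Deterministic categorical color keyed by a hash of the subject id."""
    digest = hashlib.md5(str(subject_id).encode()).digest()
    return _PALETTE[digest[0] % len(_PALETTE)]


@dataclass(frozen=True)
class SelectionState:
    """Linked-selection state: subject id -> color label."""

    selected: dict = field(default_factory=dict)

    def color_of(self, subject_id, default=DEFAULT_COLOR):
        return self.selected.get(subject_id, default)

    def __contains__(self, subject_id) -> bool:
        return subject_id in self.selected

    def ids(self) -> list:
        return sorted(self.selected)


def _save(fig, out_path):
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return str(out_path)


def parallel_coordinate_plot(
    s: ScaledMatrix,
    sel: SelectionState | None = None,
    out_path=None,
    vertical_axes: bool = False,
    ax=None,
):
    """Parallel-coordinate plot of a scaled resampling matrix.

    One unit-length parallel axis per run in run order, one polyline per
    subject, broken wherever the subject is missing from a run; selected
    subjects are drawn last in their selection colors.  By default the axes
    are horizontal and stacked vertically, values "connected downwards";
    ``vertical_axes=True`` gives the conventional layout.

    Returns (figure path or None, manifest dict).
    """
    sel = sel or SelectionState()
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(s.run_labels))))
    else:
        fig = ax.figure
    n_runs = len(s.run_labels)
    axis_pos = np.arange(n_runs)
    manifest = {"kind": "parallel_coordinates", "runs": list(s.run_labels),
                "subjects": {}}

    def xy(vals):
        return (vals, axis_pos) if not vertical_axes else (axis_pos, vals)

    for guide in (0.0, 1.0):  # unit boundary guides
        if vertical_axes:
            ax.axhline(guide, color="k", lw=0.8)
        else:
            ax.axvline(guide, color="k", lw=0.8)

    order = [i for i, sid in enumerate(s.subject_ids) if sid not in sel]
    order += [i for i, sid in enumerate(s.subject_ids) if sid in sel]
    for i in order:
        sid = s.subject_ids[i]
        vals = s.values[i]
        selected = sid in sel
        color = sel.color_of(sid) if selected else DEFAULT_COLOR
        x, y = xy(vals)
        ax.plot(x, y, color=color, lw=1.6 if selected else 0.7,
                alpha=1.0 if selected else 0.6,
                zorder=3 if selected else 2)
        gaps = int(np.isnan(vals).sum())
        segments = _segment_count(vals)
        manifest["subjects"][str(sid)] = {
            "n_points": int(np.isfinite(vals).sum()),
            "n_gaps": gaps,
            "n_segments": segments,
            "selected": selected,
            "color": matplotlib.colors.to_hex(color),
        }
    if vertical_axes:
        ax.set_xlabel("run")
        ax.set_ylabel("scaled estimate")
    else:
        ax.set_xlabel("scaled estimate")
        ax.set_ylabel("run")
        ax.invert_yaxis()  # run 1 at the top, lines connect downwards
    ax.set_title("parallel coordinates (one axis per run)")
    manifest["selection"] = [str(i) for i in sel.ids()]
    path = _save(fig, out_path) if (out_path and created) else None
    return path, manifest


def _segment_count(vals) -> int:
    finite = np.isfinite(np.asarray(vals))
    runs = 0
    prev = False
    for f in finite:
        if f and not prev:
            runs += 1
        prev = f
    return runs


def mds_plot(e: MDSEmbedding, sel: SelectionState | None = None,
             out_path=None, ax=None):
    """Labeled scatter of the first two MDS dimensions."""
    sel = sel or SelectionState()
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    pts = e.points
    manifest = {"kind": "mds", "subjects": {}}
    for i, sid in enumerate(e.labels):
        selected = sid in sel
        color = sel.color_of(sid) if selected else DEFAULT_COLOR
        ax.scatter(pts[i, 0], pts[i, 1], color=color,
                   s=46 if selected else 22, zorder=3 if selected else 2)
        ax.annotate(str(sid), (pts[i, 0], pts[i, 1]), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
        manifest["subjects"][str(sid)] = {
            "x": float(pts[i, 0]),
            "y": float(pts[i, 1]),
            "selected": selected,
            "color": matplotlib.colors.to_hex(color),
        }
    frac = e.explained_fraction
    ax.set_xlabel(f"MDS 1 ({100 * frac[0]:.1f}% of eigenvalue sum)")
    if pts.shape[1] > 1:
        ax.set_ylabel(f"MDS 2 ({100 * frac[1]:.1f}% of eigenvalue sum)")
    ax.set_title("classical MDS of resampling matrix")
    manifest["explained_fraction"] = [float(f) for f in frac]
    manifest["selection"] = [str(i) for i in sel.ids()]
    path = _save(fig, out_path) if (out_path and created) else None
    return path, manifest


def design_plot(design: RunDesign, out_path=None):
    """Run-by-subject view of a resampling design.

    cdd: deleted subject vs run (a staircase when deletion is sequential);
    bootstrap: a dot for every (run, included subject) pair.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    manifest = {"kind": "design", "design_kind": design.kind,
                "n_runs": design.n_runs}
    if design.kind.startswith("cdd") and design.kind != "cdd_observation":
        xs, ys = [], []
        for r, run in enumerate(design.runs, start=1):
            for sid in run.excluded:
                xs.append(r)
                ys.append(sid)
        ax.plot(xs, ys, "o-", ms=3, lw=0.7)
        ax.set_ylabel("deleted subject")
        manifest["n_deletions"] = len(xs)
    else:
        table = design.inclusion_counts()
        xs, ys = [], []
        for r, run_id in enumerate(table.index, start=1):
            for sid in table.columns[table.loc[run_id] > 0]:
                xs.append(r)
                ys.append(sid)
        ax.plot(xs, ys, "o", ms=2, alpha=0.6)
        ax.set_ylabel("included subject")
        manifest["n_inclusion_dots"] = len(xs)
    ax.set_xlabel("run")
    ax.set_title(f"resampling design: {design.kind}")
    path = _save(fig, out_path) if out_path else None
    return path, manifest


def density_plot(densities: dict, out_path=None, reference=None,
                 xlabel="value"):
    """Overlaid per-run kernel densities (one color per run)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    cmap = plt.get_cmap("viridis")
    labels = list(densities)
    for i, label in enumerate(labels):
        grid, dens = densities[label]
        if np.all(np.isnan(dens)):
            continue
        ax.plot(grid, dens, color=cmap(i / max(1, len(labels) - 1)),
                lw=0.7, alpha=0.7)
    if reference is not None:
        grid, dens = reference
        ax.plot(grid, dens, color="k", lw=2.0, label="original data")
        ax.legend()
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    ax.set_title("per-run distributions")
    manifest = {"kind": "density", "n_runs": len(labels)}
    path = _save(fig, out_path) if out_path else None
    return path, manifest


def profile_plot(data: PKDataset, sel: SelectionState | None = None,
                 out_path=None, ax=None):
    """Concentration-time polylines, one per subject."""
    sel = sel or SelectionState()
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    manifest = {"kind": "profiles", "subjects": {}}
    obs = data.observations()
    plain = [s for s in data.subject_ids if s not in sel]
    chosen = [s for s in data.subject_ids if s in sel]
    for sid in plain + chosen:
        sub = obs[obs["ID"] == sid]
        selected = sid in sel
        color = sel.color_of(sid) if selected else DEFAULT_COLOR
        ax.plot(sub["TIME"], sub["DV"], color=color,
                lw=1.8 if selected else 0.6,
                alpha=1.0 if selected else 0.5,
                zorder=3 if selected else 2)
        manifest["subjects"][str(sid)] = {
            "n_points": int(len(sub)),
            "selected": selected,
            "color": matplotlib.colors.to_hex(color),
        }
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration")
    ax.set_title("concentration-time profiles")
    manifest["selection"] = [str(i) for i in sel.ids()]
    path = _save(fig, out_path) if (out_path and created) else None
    return path, manifest


def variance_plot(variances, sel: SelectionState | None = None, out_path=None):
    """EBE variance across runs vs subject ID, selection-colored.

    ``variances`` is the DataFrame produced by diagnostics.ebe_variance.
    """
    sel = sel or SelectionState()
    fig, ax = plt.subplots(figsize=(6, 4))
    manifest = {"kind": "variance", "subjects": {}}
    for row in variances.itertuples(index=False):
        sid = row.ID
        selected = sid in sel
        color = sel.color_of(sid) if selected else "C0"
        ax.scatter(sid, row.variance, color=color,
                   s=46 if selected else 18, zorder=3 if selected else 2)
        manifest["subjects"][str(sid)] = {
            "variance": None if row.variance != row.variance
            else float(row.variance),
            "selected": selected,
        }
    ax.set_xlabel("subject ID")
    ax.set_ylabel("variance of estimate across runs")
    ax.set_title("per-subject estimate variance")
    manifest["selection"] = [str(i) for i in sel.ids()]
    path = _save(fig, out_path) if out_path else None
    return path, manifest


def linked_report(
    scaled: ScaledMatrix,
    data: PKDataset,
    embedding: MDSEmbedding,
    sel: SelectionState | None = None,
    out_dir=None,
):
    """Three-panel linked view: parallel coordinates, profiles, MDS.

    One shared SelectionState colors the same subject ids identically in
    every panel; the JSON manifest lists, per panel, the elements mapped to
    each selected subject.  Raises if the panels disagree on the subject
    universe or the selection names an absent subject.
    """
    sel = sel or SelectionState()
    uni_scaled = set(scaled.subject_ids)
    uni_data = set(data.subject_ids)
    uni_mds = set(embedding.labels)
    if not (uni_scaled == uni_data == uni_mds):
        diff = (uni_scaled ^ uni_data) | (uni_scaled ^ uni_mds)
        raise ValueError(f"subject universes disagree on ids: {sorted(diff)}")
    absent = [s for s in sel.ids() if s not in uni_data]
    if absent:
        raise ValueError(f"selection names absent subjects: {absent}")

    fig, axes = plt.subplots(1, 3, figsize=(15, 5))
    _, man_pc = parallel_coordinate_plot(scaled, sel, ax=axes[0])
    _, man_prof = profile_plot(data, sel, ax=axes[1])
    _, man_mds = mds_plot(embedding, sel, ax=axes[2])
    fig.tight_layout()

    manifest = {
        "selection": [str(i) for i in sel.ids()],
        "panels": {
            "parallel_coordinates": man_pc,
            "profiles": man_prof,
            "mds": man_mds,
        },
    }
    fig_path = manifest_path = None
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        fig_path = os.path.join(out_dir, "linked_report.png")
        _save(fig, fig_path)
        manifest_path = os.path.join(out_dir, "linked_manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)
    else:
        plt.close(fig)
    return fig_path, manifest
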