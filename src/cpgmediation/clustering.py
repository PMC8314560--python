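"""Clustered significance-frequency heatmap and analysis report.

The frequency matrix (outcomes × covariates, values = number of bootstrap
replicates in which the covariate was independently significant at p ≤ α)
is clustered hierarchically on rows and columns, then rendered as a heatmap
with dendrograms, a sequential orange colour ramp scaled 0 → n_bootstrap,
and a functional-class colour strip under the column dendrogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .mediation import MediationResult
from .panel import FUNCTIONAL_CLASSES, CpGPanel


@dataclass
class FrequencyMatrix:
    """Outcome × covariate significance counts over bootstrap replicates."""

    values: pd.DataFrame  # rows: outcomes, cols: covariates/CpGs, int counts
    n_bootstrap: int
    col_annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("row/column labels must be unique")
        v = self.values.to_numpy()
        if (v < 0).any() or (v > self.n_bootstrap).any():
            raise ValueError(f"counts must lie in [0, {self.n_bootstrap}]")

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="outcome")

    @classmethod
    def from_csv(cls, path, n_bootstrap: int, col_annotation=None) -> "FrequencyMatrix":
        df = pd.read_csv(path, index_col="outcome")
        df.index.name = None
        return cls(df, n_bootstrap, col_annotation or {})


def frequency_matrix(
    results: dict[str, MediationResult],
    model: str = "cpg+interv",
    panel: CpGPanel | None = None,
    columns: list[str] | None = None,
) -> FrequencyMatrix:
    """Assemble the frequency matrix from per-outcome mediation results.

    By default the columns are the CpG sites of ``panel`` (the figure shows
    CpG columns only); pass ``columns`` explicitly to include baseline
    covariates or the intervention.
    """
    if not results:
        raise ValueError("no mediation results given")
    rows = {}
    for outcome, res in results.items():
        freq = res.significance_frequency.get(model)
        if freq is None:
            raise KeyError(f"model {model!r} has no frequencies in {outcome!r}")
        rows[outcome] = freq
    df = pd.DataFrame(rows).T
    if columns is None and panel is not None:
        columns = [c for c in panel.cpg_ids if c in df.columns]
    if columns is not None:
        df = df[columns]
    n_boot = next(iter(results.values())).n_bootstrap
    ann = panel.classes if panel is not None else {}
    return FrequencyMatrix(df.fillna(0).astype(int), n_boot, ann)


@dataclass
class ClusterResult:
    """Row/column dendrograms and the induced leaf orders."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def _cluster_axis(X: np.ndarray, labels: list[str], metric: str, method: str):
    """Cluster one axis with deterministic label-order tie-breaking."""
    order = np.argsort(np.asarray(labels, dtype=object))
    Xs = X[order]
    sorted_labels = [labels[i] for i in order]
    Z = hierarchy.linkage(pdist(Xs, metric=metric), method=method)
    leaves = hierarchy.leaves_list(Z)
    return [sorted_labels[i] for i in leaves], Z, sorted_labels


def cluster_frequency_matrix(
    fm: FrequencyMatrix, metric: str = "euclidean", method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of rows and columns independently.

    Labels are sorted before linkage so the result is invariant to the
    input row/column order (ties broken by label). Raises on a single-row
    or single-column matrix.
    """
    if fm.values.shape[0] < 2 or fm.values.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    X = fm.values.to_numpy(dtype=float)
    row_order, row_Z, _ = _cluster_axis(X, list(fm.values.index), metric, method)
    col_order, col_Z, _ = _cluster_axis(X.T, list(fm.values.columns), metric, method)
    return ClusterResult(row_order, col_order, row_Z, col_Z)


_CLASS_COLORS = dict(zip(FUNCTIONAL_CLASSES, plt.get_cmap("tab10").colors[: len(FUNCTIONAL_CLASSES)]))


def render_heatmap(
    fm: FrequencyMatrix,
    cr: ClusterResult,
    panel: CpGPanel | None,
    path,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Render the clustered heatmap; write image(s) plus a JSON sidecar.

    The sidecar (``<path>.json``) records row/col order, the reordered count
    matrix and ``n_bootstrap``, and round-trips the frequency matrix exactly.
    Returns the written paths.
    """
    ann = dict(fm.col_annotation)
    if panel is not None:
        ann.update(panel.classes)
    unannotated = [c for c in cr.col_order if c.startswith("cg") and c not in ann]
    if unannotated:
        raise ValueError(f"functional-class annotation missing for: {unannotated}")
    vals = fm.values.loc[cr.row_order, cr.col_order]

    fig = plt.figure(figsize=(max(8, 0.28 * len(cr.col_order)), 4.5))
    gs = fig.add_gridspec(
        3, 2, width_ratios=[0.12, 1.0], height_ratios=[0.25, 0.05, 1.0],
        hspace=0.02, wspace=0.02,
    )
    ax_cden = fig.add_subplot(gs[0, 1])
    ax_strip = fig.add_subplot(gs[1, 1])
    ax_rden = fig.add_subplot(gs[2, 0])
    ax_heat = fig.add_subplot(gs[2, 1])

    with plt.rc_context({"lines.linewidth": 0.8}):
        hierarchy.dendrogram(cr.col_linkage, ax=ax_cden, no_labels=True,
                             color_threshold=0, above_threshold_color="k")
        hierarchy.dendrogram(cr.row_linkage, ax=ax_rden, no_labels=True,
                             orientation="left", color_threshold=0,
                             above_threshold_color="k")
    ax_cden.axis("off")
    ax_rden.axis("off")

    classes = [ann.get(c) for c in cr.col_order]
    strip = np.array(
        [_CLASS_COLORS.get(cl, (0.85, 0.85, 0.85)) for cl in classes]
    ).reshape(1, -1, 3)
    ax_strip.imshow(strip, aspect="auto", interpolation="nearest")
    ax_strip.axis("off")

    im = ax_heat.imshow(
        vals.to_numpy(float), aspect="auto", cmap="Oranges",
        vmin=0, vmax=fm.n_bootstrap, interpolation="nearest",
    )
    ax_heat.set_yticks(range(len(cr.row_order)), cr.row_order, fontsize=8)
    ax_heat.set_xticks(range(len(cr.col_order)), cr.col_order,
                       rotation=90, fontsize=6)
    cbar = fig.colorbar(im, ax=ax_heat, fraction=0.03, pad=0.01)
    cbar.set_label(f"significant in k / {fm.n_bootstrap} bootstrap replicates",
                   fontsize=7)
    handles = [Patch(color=_CLASS_COLORS[c], label=c) for c in FUNCTIONAL_CLASSES]
    fig.legend(handles=handles, loc="lower center", ncol=4, fontsize=6,
               frameon=False, bbox_to_anchor=(0.5, -0.12))

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt in formats:
        out = path.with_suffix(f".{fmt}")
        fig.savefig(out, bbox_inches="tight", dpi=150, metadata={})
        written.append(out)
    plt.close(fig)

    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "row_order": cr.row_order,
                "col_order": cr.col_order,
                "n_bootstrap": fm.n_bootstrap,
                "values": {r: {c: int(vals.loc[r, c]) for c in cr.col_order}
                           for r in cr.row_order},
                "col_annotation": {c: ann.get(c) for c in cr.col_order},
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    written.append(sidecar)
    return written


def parse_sidecar(path) -> tuple[FrequencyMatrix, list[str], list[str]]:
    """Re-read a heatmap sidecar back into a FrequencyMatrix + orders."""
    with open(path) as fh:
        d = json.load(fh)
    df = pd.DataFrame(d["values"]).T.loc[d["row_order"], d["col_order"]]
    ann = {k: v for k, v in d["col_annotation"].items() if v is not None}
    return FrequencyMatrix(df.astype(int), d["n_bootstrap"], ann), d["row_order"], d["col_order"]


def report(
    results: dict[str, MediationResult],
    fm: FrequencyMatrix,
    cr: ClusterResult,
    path,
    panel: CpGPanel | None = None,
    heatmap_file: str | None = None,
    top_k: int = 5,
) -> Path:
    """Write a Markdown report: corrected-R²/fold table per outcome, the
    mediation flags with the decision rule stated, top CpGs by frequency,
    and the heatmap reference. Deterministic given identical inputs."""
    if not results:
        raise ValueError("empty results set: nothing to report")
    lines: list[str] = ["# Methylation mediation analysis report", ""]
    lines += [
        "Explanatory power is the bootstrap optimism-corrected R² of random-",
        "forest regressions, Rubin-pooled across imputations. Fold-increase",
        "compares models with the CpG panel against baseline-risk-factor",
        "models at the same intervention setting.",
        "",
        "| Outcome | R² (no interv.) | Fold vs baseline | R² (with interv.) | Fold vs baseline+interv. |",
        "|---|---|---|---|---|",
    ]
    for outcome, res in results.items():
        f1 = res.fold_increase_without_intervention
        f2 = res.fold_increase_with_intervention
        lines.append(
            f"| {outcome} | {res.r2_corrected['cpg']:.3f} | "
            f"{'–' if f1 is None else f'{f1:.3f}'} | "
            f"{res.r2_corrected['cpg+interv']:.3f} | "
            f"{'–' if f2 is None else f'{f2:.3f}'} |"
        )
    lines += ["", "## Intervention significance and mediation flags", ""]
    lines += [
        "Rule: mediation is flagged when the intervention is significant in",
        "≥ threshold bootstrap replicates of the baseline-only model, its",
        "frequency drops when the CpG panel is added, and at least one CpG",
        "reaches the threshold in the with-CpG model.",
        "",
        "| Outcome | Interv. freq (baseline) | Interv. freq (with CpGs) | Threshold | Mediation |",
        "|---|---|---|---|---|",
    ]
    for outcome, res in results.items():
        lines.append(
            f"| {outcome} | {res.intervention_frequency_baseline}/{res.n_bootstrap} | "
            f"{res.intervention_frequency_with_cpg}/{res.n_bootstrap} | "
            f"{res.mediation_threshold} | {'yes' if res.mediation_flag else 'no'} |"
        )
    lines += ["", "## Top CpG sites per outcome (by bootstrap frequency)", ""]
    genes = panel.genes if panel is not None else {}
    for outcome in fm.values.index:
        top = fm.values.loc[outcome].sort_values(ascending=False).head(top_k)
        items = ", ".join(
            f"{c} ({genes.get(c, '?')}): {v}" for c, v in top.items()
        )
        lines.append(f"- **{outcome}**: {items}")
    lines += ["", "## Clustering", ""]
    lines.append(f"- Row order: {', '.join(cr.row_order)}")
    lines.append(f"- Column order: {', '.join(cr.col_order)}")
    if heatmap_file:
        lines += ["", f"![clustered frequency heatmap]({heatmap_file})"]
    for outcome, res in results.items():
        for note in res.notes:
            lines.append(f"- note ({outcome}): {note}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path
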