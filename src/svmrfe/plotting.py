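"""Figures: pseudo-sample decision-curve panels and KPCA vector fields.

Every figure's underlying table is also written as CSV next to it, so no
number exists only in a figure.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_decision_curves", "plot_growth_field"]


def plot_decision_curves(table: pd.DataFrame, path: str | Path,
                         ncols: int = 6) -> Path:
    """Panel per variable: raw pseudo-sample decision curves plus the smoothed
    mean and 95% band (when present in the table from ``export_curves``)."""
    path = Path(path)
    variables = list(table["variable"].drop_duplicates())
    n = len(variables)
    ncols = min(ncols, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 1.8 * nrows),
                             sharex=True, sharey=True, squeeze=False)
    for k, var in enumerate(variables):
        ax = axes[k // ncols][k % ncols]
        g = table[table["variable"] == var]
        for _, rep in g.groupby("replicate"):
            ax.plot(rep["z"], rep["decision"], color="grey", alpha=0.25, lw=0.6)
        if "smoothed" in g.columns and g["smoothed"].notna().any():
            s = g.drop_duplicates("z").sort_values("z")
            ax.fill_between(s["z"], s["lo95"], s["hi95"], color="tab:blue", alpha=0.3)
            ax.plot(s["z"], s["smoothed"], color="tab:blue", lw=1.2)
        ax.set_title(var, fontsize=8)
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.supxlabel("pseudo-sample value")
    fig.supylabel("decision value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    table.to_csv(path.with_suffix(".csv"), index=False)
    return path


def plot_growth_field(scores: np.ndarray, fields: dict[str, np.ndarray],
                      path: str | Path, status_colors: np.ndarray | None = None,
                      arrow_length: float = 0.15) -> Path:
    """Samples on the two leading KPCA axes with fixed-length growth arrows.

    ``fields`` maps a label to an (n, 2) array of tangent vectors; arrows are
    rescaled to a fixed display length.  ``status_colors`` colours the sample
    points (e.g. red = event, green = non-event, blue = censored early).
    """
    path = Path(path)
    scores = np.asarray(scores, float)
    span = max(np.ptp(scores[:, 0]), np.ptp(scores[:, 1]), 1e-9)
    L = arrow_length * span
    nf = len(fields)
    fig, axes = plt.subplots(1, nf, figsize=(3.2 * nf, 3.2), squeeze=False)
    tables = []
    for k, (label, vec) in enumerate(fields.items()):
        ax = axes[0][k]
        vec = np.asarray(vec, float)
        nrm = np.linalg.norm(vec, axis=1)
        safe = np.where(nrm < 1e-12, 1.0, nrm)
        arrows = L * vec / safe[:, None]
        c = status_colors if status_colors is not None else "black"
        ax.scatter(scores[:, 0], scores[:, 1], s=12, c=c, alpha=0.8, zorder=3)
        ax.quiver(scores[:, 0], scores[:, 1], arrows[:, 0], arrows[:, 1],
                  angles="xy", scale_units="xy", scale=1, width=0.004, alpha=0.7)
        ax.set_title(label, fontsize=9)
        ax.set_xlabel("PC1")
        if k == 0:
            ax.set_ylabel("PC2")
        t = pd.DataFrame({"label": label, "pc1": scores[:, 0], "pc2": scores[:, 1],
                          "du": vec[:, 0], "dv": vec[:, 1]})
        tables.append(t)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    pd.concat(tables, ignore_index=True).to_csv(path.with_suffix(".csv"), index=False)
    return path
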