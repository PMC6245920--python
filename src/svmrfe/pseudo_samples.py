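"""Pseudo-sample RFE: rank variables by the spread of the SVM decision curve.

A *pseudo-sample grid* for variable j varies that variable over a fixed range
of equidistant values while holding every other variable at a baseline (0 on
standardized data).  Passing the grid through a fitted SVM traces how the
decision value responds to variable j alone; the robust spread of that curve
(median absolute deviation, scaled by 1.4826 for consistency with the normal
standard deviation) scores the variable's relevance.  Recursive elimination
of the lowest-MAD variable yields the full ranking, and the first-iteration
curves are the method's visualization output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelSpec
from .psvm import LabeledSet, PSVMResults
from .rfe import RFEResults, _BaseRFE
from .survival import SurvivalDataset

__all__ = [
    "MAD_CONSISTENCY",
    "PseudoSampleGrid",
    "DecisionCurve",
    "make_grid",
    "decision_curve",
    "mad_score",
    "PseudoSampleRFE",
    "rank_pseudo_samples",
    "export_curves",
]

#: Normal-consistency constant 1/Phi^{-1}(3/4): makes the MAD an unbiased
#: estimate of the standard deviation for Gaussian data.
MAD_CONSISTENCY = 1.4826

DEFAULT_Z = np.linspace(-2.0, 2.0, 50)  # 50 equidistant points on [-2, 2]


@dataclass
class PseudoSampleGrid:
    """q x p matrix varying one variable over ``z_values``, others at baseline."""

    variable: int
    z_values: np.ndarray
    baseline: np.ndarray
    matrix: np.ndarray


@dataclass
class DecisionCurve:
    """Decision values of a fitted SVM along one variable's pseudo-sample grid."""

    variable: str
    z_values: np.ndarray
    decision_values: np.ndarray


def make_grid(p: int, variable: int, z_values: np.ndarray | None = None,
              baseline: np.ndarray | float = 0.0) -> PseudoSampleGrid:
    """Build the pseudo-sample matrix for one variable (0-based index).

    ``z_values`` defaults to 50 equidistant points on [-2, 2], the natural
    range for standardized predictors.  ``baseline`` may be a scalar or a
    p-vector (e.g. per-variable medians).
    """
    if not 0 <= variable < p:
        raise ValueError(f"variable index {variable} out of range for p={p}")
    z = DEFAULT_Z.copy() if z_values is None else np.asarray(z_values, dtype=float).ravel()
    if z.size < 2:
        raise ValueError("need at least two pseudo-sample values")
    if np.any(np.diff(z) <= 0):
        raise ValueError("z_values must be strictly ascending")
    base = np.full(p, float(baseline)) if np.isscalar(baseline) else np.asarray(baseline, dtype=float)
    if base.shape != (p,):
        raise ValueError("baseline must be scalar or length-p")
    M = np.tile(base, (z.size, 1))
    M[:, variable] = z
    return PseudoSampleGrid(variable=variable, z_values=z, baseline=base, matrix=M)


def decision_curve(model: PSVMResults, grid: PseudoSampleGrid,
                   name: str | None = None) -> DecisionCurve:
    """Decision values (not thresholded classes) along a pseudo-sample grid."""
    D = model.decision_function(grid.matrix, standardized=True)
    return DecisionCurve(
        variable=name if name is not None else f"V{grid.variable + 1}",
        z_values=grid.z_values,
        decision_values=D,
    )


def mad_score(D: np.ndarray, c: float = MAD_CONSISTENCY) -> float:
    """Median absolute deviation ``c * median(|D - median(D)|)``."""
    D = np.asarray(D, dtype=float).ravel()
    if D.size == 0:
        raise ValueError("empty decision-value vector")
    return float(c * np.median(np.abs(D - np.median(D))))


class PseudoSampleRFE(_BaseRFE):
    """RFE driven by pseudo-sample decision-curve MAD.

    Parameters
    ----------
    data : LabeledSet or SurvivalDataset
        Survival data is first landmark-encoded; predictors are standardized
        once up front (grids are built in standardized coordinates).
    kernel, C, Ctilde :
        Fixed (pre-tuned) SVM hyperparameters, used at every iteration.
    z_values : array, optional
        Pseudo-sample range; default 50 equidistant points on [-2, 2].
    baseline : scalar or vector
        Value at which non-evaluated variables are held (default 0, the
        post-standardization mean; medians or any biologically meaningful
        profile may be supplied instead).
    """

    method = "pseudo-samples"

    def __init__(self, data: LabeledSet | SurvivalDataset, kernel: KernelSpec = KernelSpec(),
                 C: float = 1.0, Ctilde: float = 1.0, z_values: np.ndarray | None = None,
                 baseline: np.ndarray | float = 0.0, min_variables: int = 1):
        super().__init__(data, kernel=kernel, C=C, Ctilde=Ctilde, min_variables=min_variables)
        self.z_values = DEFAULT_Z.copy() if z_values is None else np.asarray(z_values, float)
        self.baseline = baseline
        self._first_curves: list[DecisionCurve] | None = None

    def _criterion(self, model: PSVMResults, sub: LabeledSet) -> np.ndarray:
        p = sub.X.shape[1]
        base = self.baseline
        if not np.isscalar(base):
            # subset a vector baseline to the surviving columns
            full = np.asarray(base, float)
            idx = [self.data.names.index(n) for n in sub.names]
            base = full[idx]
        curves = []
        scores = np.empty(p)
        for j in range(p):
            grid = make_grid(p, j, self.z_values, base)
            curve = decision_curve(model, grid, name=sub.names[j])
            scores[j] = mad_score(curve.decision_values)
            curves.append(curve)
        if self._first_curves is None:
            self._first_curves = curves
        return scores

    def fit(self) -> RFEResults:
        self._first_curves = None
        res = super().fit()
        res.extras["first_iteration_curves"] = self._first_curves or []
        return res


def rank_pseudo_samples(data: LabeledSet | SurvivalDataset, kernel: KernelSpec = KernelSpec(),
                        C: float = 1.0, Ctilde: float = 1.0,
                        z_values: np.ndarray | None = None,
                        baseline: np.ndarray | float = 0.0) -> RFEResults:
    """One-call pseudo-sample ranking; see :class:`PseudoSampleRFE`."""
    return PseudoSampleRFE(data, kernel=kernel, C=C, Ctilde=Ctilde,
                           z_values=z_values, baseline=baseline).fit()


def export_curves(curves: list[DecisionCurve] | list[list[DecisionCurve]],
                  smooth: bool = True, frac: float = 0.5) -> pd.DataFrame:
    """Long-format table of decision curves, optionally with a smoothed band.

    ``curves`` is either a flat list (one replicate) or a list of per-replicate
    lists.  The returned frame has columns (variable, z, decision, replicate)
    plus, when smoothing is on, (smoothed, lo95, hi95): a LOESS fit of the
    replicate mean and a normal-approximation 95% band across replicates.
    Smoothing is presentation-only — ranking always uses raw decision values.
    """
    if not curves:
        raise ValueError("no curves to export")
    if isinstance(curves[0], DecisionCurve):
        reps: list[list[DecisionCurve]] = [curves]  # type: ignore[list-item]
    else:
        reps = curves  # type: ignore[assignment]
    rows = []
    for r, rep in enumerate(reps):
        for c in rep:
            for z, d in zip(c.z_values, c.decision_values):
                rows.append({"variable": c.variable, "z": z, "decision": d, "replicate": r})
    df = pd.DataFrame(rows)
    if not smooth:
        return df
    from statsmodels.nonparametric.smoothers_lowess import lowess

    out = []
    for var, g in df.groupby("variable", sort=False):
        piv = g.pivot_table(index="z", columns="replicate", values="decision")
        mean = piv.mean(axis=1).to_numpy()
        nrep = piv.shape[1]
        se = piv.std(axis=1, ddof=1).to_numpy() / np.sqrt(nrep) if nrep > 1 else np.zeros(len(piv))
        z = piv.index.to_numpy()
        sm = lowess(mean, z, frac=frac, return_sorted=False)
        sub = pd.DataFrame(
            {"variable": var, "z": z, "smoothed": sm, "lo95": sm - 1.96 * se, "hi95": sm + 1.96 * se}
        )
        out.append(sub)
    return df.merge(pd.concat(out, ignore_index=True), on=["variable", "z"], how="left")
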