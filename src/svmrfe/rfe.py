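"""Recursive feature elimination harness and the Guyon reference criteria.

``run_rfe`` is the generic backward-elimination loop shared by all ranking
methods: at every iteration the model is refit on the surviving variables
(hyperparameters stay fixed), a per-variable criterion is computed, and the
variable minimizing the criterion is removed.  Variables are ranked by
removal order — rank 1 is the survivor (most relevant), rank p the first
variable removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from .kernels import KernelSpec, kernel_matrix
from .psvm import LabeledSet, PSVMResults, fit_psvm
from .preprocessing import standardize
from .survival import SurvivalDataset, encode_landmark

__all__ = [
    "RankResult",
    "run_rfe",
    "guyon_linear_criterion",
    "guyon_nonlinear_criterion",
    "GuyonRFE",
    "RFEResults",
]


@dataclass
class RankResult:
    """Variable ranks (1 = most relevant = eliminated last) plus audit trace.

    ``trace`` holds one record per elimination with the criterion value of
    every surviving variable at that iteration, so the removal choice can be
    audited after the fact.
    """

    ranks: dict[str, int]
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = sorted(self.ranks.values())
        if vals != list(range(1, len(vals) + 1)):
            raise ValueError("ranks must be a permutation of 1..p")

    def rank_of(self, name: str) -> int:
        return self.ranks[name]

    def ordered(self) -> list[str]:
        """Variable names from most to least relevant."""
        return [k for k, _ in sorted(self.ranks.items(), key=lambda kv: kv[1])]

    def to_frame(self) -> pd.DataFrame:
        p = len(self.ranks)
        rows = []
        removed_at = {rec["removed"]: rec for rec in self.trace}
        for name, rank in sorted(self.ranks.items(), key=lambda kv: kv[1]):
            rec = removed_at.get(name)
            rows.append(
                {
                    "variable": name,
                    "rank": rank,
                    "iteration_removed": rec["iteration"] if rec else p,
                    "criterion_value": rec["criterion"][name] if rec else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"ranks": self.ranks, "trace": self.trace}, default=float, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def run_rfe(
    data: LabeledSet,
    refit: Callable[[LabeledSet], Any],
    criterion: Callable[[Any, LabeledSet], np.ndarray],
    min_variables: int = 1,
) -> RankResult:
    """Generic RFE loop.

    Parameters
    ----------
    data : LabeledSet
        Full (already standardized/encoded) training set.
    refit : callable
        Maps the surviving-variable LabeledSet to a fitted model.
    criterion : callable
        Maps (model, surviving LabeledSet) to an array of per-variable scores
        (lower = less relevant).  Ties are broken toward the lowest index.
    min_variables : int
        Stop when this many variables remain (default 1, full ranking).
    """
    p = data.X.shape[1]
    if p < 1:
        raise ValueError("need at least one variable")
    surviving = list(range(p))
    ranks: dict[str, int] = {}
    trace: list[dict] = []
    iteration = 0
    while len(surviving) > max(min_variables, 1):
        iteration += 1
        sub = data.select_columns(surviving)
        try:
            model = refit(sub)
            scores = np.asarray(criterion(model, sub), dtype=float)
        except Exception as exc:  # annotate failures with the iteration index
            raise RuntimeError(f"RFE iteration {iteration} failed: {exc}") from exc
        if scores.shape[0] != len(surviving):
            raise ValueError("criterion must return one score per surviving variable")
        drop_local = int(np.argmin(scores))  # argmin takes the first (lowest index) on ties
        removed = surviving[drop_local]
        ranks[data.names[removed]] = len(surviving)
        trace.append(
            {
                "iteration": iteration,
                "removed": data.names[removed],
                "criterion": {data.names[surviving[i]]: float(scores[i]) for i in range(len(surviving))},
            }
        )
        surviving.pop(drop_local)
    # survivors keep the best ranks, ordered by column index
    for r, idx in enumerate(sorted(surviving)):
        ranks[data.names[idx]] = r + 1
    return RankResult(ranks=ranks, trace=trace)


def guyon_linear_criterion(results: PSVMResults, j: int | None = None) -> np.ndarray | float:
    """Guyon's linear-kernel criterion ``w_j^2`` from the primal weights."""
    w = results.linear_weights()
    w2 = w**2
    return w2 if j is None else float(w2[j])


def guyon_nonlinear_criterion(results: PSVMResults, j: int | None = None) -> np.ndarray | float:
    """Cost-function sensitivity criterion for arbitrary kernels.

    ``dJ(j) = 1/2 |a' H a - a' H^(-j) a|`` with ``H_ik = y_i y_k k(x_i, x_k)``
    and ``H^(-j)`` the same matrix with variable j removed from the kernel,
    dual coefficients held fixed (no retraining per candidate).  Under the
    linear kernel this reduces algebraically to ``w_j^2 / 2``.
    """
    alpha = results.alpha
    y = results.y_support
    X = results.support_X
    spec = results.kernel
    ay = alpha * y  # = rho
    if spec.kind == "gaussian":
        K = kernel_matrix(X, spec=spec)
        base = ay @ K @ ay
        p = X.shape[1]
        out = np.empty(p)
        for a in range(p):
            d2a = (X[:, a][:, None] - X[:, a][None, :]) ** 2
            Km = K * np.exp(d2a / spec.sigma)  # kernel with variable a removed
            out[a] = 0.5 * abs(base - ay @ Km @ ay)
    else:
        p = X.shape[1]
        out = np.empty(p)
        for a in range(p):
            contrib = np.outer(X[:, a], X[:, a])
            out[a] = 0.5 * abs(ay @ contrib @ ay)
    return out if j is None else float(out[j])


class RFEResults:
    """Outcome of a recursive-elimination run: ranks, trace and extras."""

    def __init__(self, rank_result: RankResult, method: str, extras: dict | None = None):
        self.rank_result = rank_result
        self.method = method
        self.extras = extras or {}

    @property
    def ranks(self) -> dict[str, int]:
        return self.rank_result.ranks

    def summary(self) -> pd.DataFrame:
        df = self.rank_result.to_frame()
        df.insert(0, "method", self.method)
        return df


class _BaseRFE:
    """Shared machinery: landmark encoding, one-time standardization, refits."""

    method = "base"

    def __init__(self, data: LabeledSet | SurvivalDataset, kernel: KernelSpec = KernelSpec(),
                 C: float = 1.0, Ctilde: float = 1.0, min_variables: int = 1):
        if isinstance(data, SurvivalDataset):
            data = encode_landmark(data)
        Xs, scaler = standardize(data.X)
        self.data = LabeledSet(X=Xs, y=data.y, pi=data.pi, names=list(data.names))
        self.scaler = scaler
        self.kernel = kernel
        self.C = C
        self.Ctilde = Ctilde
        self.min_variables = min_variables

    def _refit(self, sub: LabeledSet) -> PSVMResults:
        return fit_psvm(sub, kernel=self.kernel, C=self.C, Ctilde=self.Ctilde, standardize=False)

    def _criterion(self, model: PSVMResults, sub: LabeledSet) -> np.ndarray:
        raise NotImplementedError

    def fit(self) -> RFEResults:
        rr = run_rfe(self.data, self._refit, self._criterion, min_variables=self.min_variables)
        return RFEResults(rr, method=self.method, extras=self._extras())

    def _extras(self) -> dict:
        return {}


class GuyonRFE(_BaseRFE):
    """Classical SVM-RFE: linear weight criterion or cost-sensitivity criterion.

    With a linear kernel the criterion is ``w_j^2``; with any other kernel the
    non-linear cost-function sensitivity is used.
    """

    method = "guyon"

    def _criterion(self, model: PSVMResults, sub: LabeledSet) -> np.ndarray:
        if self.kernel.kind == "linear":
            return np.asarray(guyon_linear_criterion(model))
        return np.asarray(guyon_nonlinear_criterion(model))
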