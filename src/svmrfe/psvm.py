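"""Probabilistic soft-margin SVM for binary and censored outcomes.

The model is a weighted C-SVM in which every *certain* sample (class
probability pi in {0, 1}) enters with misclassification cost ``C`` while every
*uncertain* sample (pi strictly between 0 and 1, e.g. a subject censored
before the landmark time) enters the dual problem twice — once as class +1
with cost ``Ctilde * pi`` and once as class -1 with cost ``Ctilde * (1 - pi)``.
With all samples certain this reduces exactly to the standard soft-margin
C-SVM.  The dual quadratic program

    min  1/2 a' Q a - 1' a   s.t.  0 <= a_i <= U_i,  y' a = 0,
    Q_ij = y_i y_j k(x_i, x_j)

is solved by sequential minimal optimization with maximal-violating-pair
working-set selection.

The class convention throughout the package is event = -1, non-event = +1,
with ``pi`` the probability of membership in class +1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelSpec, kernel_matrix
from .preprocessing import Standardizer

__all__ = ["LabeledSet", "ProbabilisticSVM", "PSVMResults", "fit_psvm", "decision_value"]


@dataclass
class LabeledSet:
    """Predictors plus (possibly uncertain) binary class membership.

    Attributes
    ----------
    X : (n, p) ndarray
        Predictor matrix (standardized or raw; models standardize by default).
    y : (n,) ndarray of {-1, +1}
        Hard class labels.  For uncertain samples this is the more probable
        class (ties resolved toward +1).
    pi : (n,) ndarray in [0, 1]
        Probability that the sample belongs to class +1.  ``pi in {0, 1}``
        marks a certain sample.
    names : list of str
        Column names for the predictors.
    """

    X: np.ndarray
    y: np.ndarray
    pi: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        n = self.X.shape[0]
        if self.y.shape[0] != n or self.pi.shape[0] != n:
            raise ValueError("X, y and pi must have matching first dimension")
        if np.isnan(self.X).any() or np.isnan(self.pi).any():
            raise ValueError("missing values not allowed")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("labels must be in {-1, +1}")
        if self.pi.min() < -1e-12 or self.pi.max() > 1 + 1e-12:
            raise ValueError("pi must lie in [0, 1]")
        self.pi = np.clip(self.pi, 0.0, 1.0)
        cert = self.certain
        if np.any(cert & (self.pi == 1.0) & (self.y != 1.0)) or np.any(
            cert & (self.pi == 0.0) & (self.y != -1.0)
        ):
            raise ValueError("labels inconsistent with certain pi values")
        if not self.names:
            self.names = [f"V{j + 1}" for j in range(self.X.shape[1])]

    @property
    def certain(self) -> np.ndarray:
        return (self.pi <= 1e-12) | (self.pi >= 1 - 1e-12)

    @classmethod
    def from_labels(cls, X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> "LabeledSet":
        """Build an all-certain set from hard labels in {-1, +1}."""
        y = np.asarray(y, dtype=float).ravel()
        return cls(X=X, y=y, pi=(y + 1) / 2, names=list(names) if names else [])

    def select_columns(self, idx: list[int]) -> "LabeledSet":
        return LabeledSet(
            X=self.X[:, idx], y=self.y.copy(), pi=self.pi.copy(), names=[self.names[j] for j in idx]
        )


class SolverError(RuntimeError):
    pass


def _smo(Q: np.ndarray, y: np.ndarray, upper: np.ndarray, tol: float = 1e-8,
         max_iter: int = 50_000, stall_tol: float = 1e-4) -> tuple[np.ndarray, float, int]:
    """Solve the box-constrained SVM dual by SMO.

    Returns ``(alpha, b, n_iter)``.  ``b`` is taken as the mean of
    ``y_i - f0(x_i)`` over margin support vectors (0 < a_i < U_i) and falls
    back to the midpoint of the two KKT extremes when none exist.

    Duplicated training points (as produced by the uncertain-sample
    expansion) can make the dual degenerate enough that the working-set
    update cycles just above ``tol``; a solution whose KKT violation is
    below ``stall_tol`` is then accepted with a warning rather than raising.
    """
    n = len(y)
    alpha = np.zeros(n)
    grad = -np.ones(n)  # Q @ alpha - 1
    tau = 1e-12
    it = 0
    for it in range(1, max_iter + 1):
        yg = -y * grad
        up = ((y > 0) & (alpha < upper - 1e-14)) | ((y < 0) & (alpha > 1e-14))
        low = ((y > 0) & (alpha > 1e-14)) | ((y < 0) & (alpha < upper - 1e-14))
        if not up.any() or not low.any():
            break
        i = np.flatnonzero(up)[np.argmax(yg[up])]
        j = np.flatnonzero(low)[np.argmin(yg[low])]
        m, M = yg[i], yg[j]
        if m - M < tol:
            break
        ai_old, aj_old = alpha[i], alpha[j]
        Ui, Uj = upper[i], upper[j]
        if y[i] != y[j]:
            quad = max(Q[i, i] + Q[j, j] + 2 * Q[i, j], tau)
            delta = (-grad[i] - grad[j]) / quad
            diff = ai_old - aj_old
            ai, aj = ai_old + delta, aj_old + delta
            if diff > 0 and aj < 0:
                aj, ai = 0.0, diff
            elif diff <= 0 and ai < 0:
                ai, aj = 0.0, -diff
            if diff > Ui - Uj:
                if ai > Ui:
                    ai, aj = Ui, Ui - diff
            else:
                if aj > Uj:
                    aj, ai = Uj, Uj + diff
        else:
            quad = max(Q[i, i] + Q[j, j] - 2 * Q[i, j], tau)
            delta = (grad[i] - grad[j]) / quad
            s = ai_old + aj_old
            ai, aj = ai_old - delta, aj_old + delta
            if s > Ui:
                if ai > Ui:
                    ai, aj = Ui, s - Ui
            else:
                if aj < 0:
                    aj, ai = 0.0, s
            if s > Uj:
                if aj > Uj:
                    aj, ai = Uj, s - Uj
            else:
                if ai < 0:
                    ai, aj = 0.0, s
        alpha[i], alpha[j] = ai, aj
        grad += Q[:, i] * (ai - ai_old) + Q[:, j] * (aj - aj_old)
    else:
        if m - M < stall_tol:
            import warnings

            warnings.warn(
                f"SMO stalled at KKT violation {m - M:.2e} after {max_iter} iterations "
                f"(target {tol}); accepting near-optimal solution"
            )
        else:
            raise SolverError(
                f"SMO did not reach KKT tolerance {tol} within {max_iter} iterations "
                f"(violation {m - M:.3e})"
            )
    # offset
    f0 = y * (grad + 1.0)  # f0_i = sum_j alpha_j y_j K_ij
    free = (alpha > 1e-8) & (alpha < upper - 1e-8)
    if free.any():
        b = float(np.mean(y[free] - f0[free]))
    else:
        yg = -y * grad
        up = ((y > 0) & (alpha < upper - 1e-14)) | ((y < 0) & (alpha > 1e-14))
        low = ((y > 0) & (alpha > 1e-14)) | ((y < 0) & (alpha < upper - 1e-14))
        hi = yg[up].max() if up.any() else 0.0
        lo = yg[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return alpha, b, it


class ProbabilisticSVM:
    """Kernel SVM accepting class-membership probabilities.

    Parameters
    ----------
    data : LabeledSet
        Predictors, labels and membership probabilities.
    kernel : KernelSpec
    C : float
        Misclassification cost for certain samples.
    Ctilde : float
        Cost multiplier for uncertain samples (each contributes with costs
        ``Ctilde*pi`` as class +1 and ``Ctilde*(1-pi)`` as class -1).
    standardize : bool
        If True (default) predictors are centered/scaled before training and
        the scaling is stored for prediction on raw inputs.

    Examples
    --------
    >>> import numpy as np
    >>> from svmrfe.psvm import LabeledSet, ProbabilisticSVM
    >>> X = np.array([[-1.0], [1.0]]); y = np.array([-1.0, 1.0])
    >>> res = ProbabilisticSVM(LabeledSet.from_labels(X, y), C=100.0,
    ...                        standardize=False).fit()
    >>> np.sign(res.decision_function(X))
    array([-1.,  1.])
    """

    def __init__(self, data: LabeledSet, kernel: KernelSpec = KernelSpec(),
                 C: float = 1.0, Ctilde: float = 1.0, standardize: bool = True):
        if C <= 0 or Ctilde <= 0:
            raise ValueError("C and Ctilde must be positive")
        self.data = data
        self.kernel = kernel
        self.C = float(C)
        self.Ctilde = float(Ctilde)
        self.standardize = standardize

    def _expand(self, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Duplicate uncertain samples, one row per candidate class."""
        d = self.data
        cert = d.certain
        rows, ys, costs = [], [], []
        for i in range(Xs.shape[0]):
            if cert[i]:
                rows.append(Xs[i]); ys.append(d.y[i]); costs.append(self.C)
            else:
                rows.append(Xs[i]); ys.append(1.0); costs.append(self.Ctilde * d.pi[i])
                rows.append(Xs[i]); ys.append(-1.0); costs.append(self.Ctilde * (1.0 - d.pi[i]))
        X = np.asarray(rows); y = np.asarray(ys); U = np.asarray(costs)
        keep = U > 1e-12
        return X[keep], y[keep], U[keep]

    def fit(self, tol: float = 1e-8, max_iter: int = 50_000) -> "PSVMResults":
        d = self.data
        cert = d.certain
        mass_pos = np.sum(d.pi) if (~cert).any() else np.sum(d.y[cert] > 0)
        if d.X.shape[0] < 2:
            raise ValueError("need at least two samples")
        has_pos = np.any(d.y[cert] > 0) or np.any(d.pi[~cert] > 1e-12)
        has_neg = np.any(d.y[cert] < 0) or np.any(d.pi[~cert] < 1 - 1e-12)
        if not (has_pos and has_neg):
            raise ValueError("both classes must carry positive mass")
        del mass_pos
        if self.standardize:
            scaler = Standardizer.fit(d.X)
            Xs = scaler.transform(d.X)
        else:
            p = d.X.shape[1]
            scaler = Standardizer(center=np.zeros(p), scale=np.ones(p))
            Xs = np.asarray(d.X, dtype=float)
        Xe, ye, Ue = self._expand(Xs)
        K = kernel_matrix(Xe, spec=self.kernel)
        Q = (ye[:, None] * ye[None, :]) * K
        alpha, b, n_iter = _smo(Q, ye, Ue, tol=tol, max_iter=max_iter)
        sv = alpha > 1e-10
        return PSVMResults(
            model=self,
            alpha=alpha[sv],
            y_support=ye[sv],
            support_X=Xe[sv],
            b=b,
            scaler=scaler,
            n_iter=n_iter,
        )


class PSVMResults:
    """Fitted probabilistic SVM: dual coefficients, offset and kernel expansion."""

    def __init__(self, model: ProbabilisticSVM, alpha: np.ndarray, y_support: np.ndarray,
                 support_X: np.ndarray, b: float, scaler: Standardizer, n_iter: int):
        self.model = model
        self.alpha = alpha
        self.y_support = y_support
        self.support_X = support_X
        self.b = b
        self.scaler = scaler
        self.n_iter = n_iter

    @property
    def rho(self) -> np.ndarray:
        """Signed dual coefficients ``rho_i = alpha_i * y_i``."""
        return self.alpha * self.y_support

    @property
    def kernel(self) -> KernelSpec:
        return self.model.kernel

    def decision_function(self, X: np.ndarray, standardized: bool = False) -> np.ndarray:
        """Decision values ``f(x) = sum_i rho_i k(x_i, x) + b``.

        The magnitude is the (kernel-space) distance of ``x`` from the margin;
        the sign is the predicted class.  Inputs are passed through the stored
        scaling unless ``standardized=True``.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_X.shape[1]:
            raise ValueError(
                f"dimension mismatch: got {X.shape[1]} columns, model has {self.support_X.shape[1]}"
            )
        Z = X if standardized else self.scaler.transform(X)
        if self.alpha.size == 0:
            return np.full(Z.shape[0], self.b)
        K = kernel_matrix(Z, self.support_X, self.model.kernel)
        return K @ self.rho + self.b

    def decision_gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient ``D_a f`` of the decision function at a standardized point.

        Chain rule on the kernel expansion: for the Gaussian kernel
        ``D_a f(x) = sum_j rho_j (2/sigma)(x_j^a - x^a) k(x_j, x)``; for the
        linear kernel it is the fixed weight vector ``w = sum_j rho_j x_j``.
        """
        from .kernels import kernel_gradient

        G = kernel_gradient(np.asarray(x, float).ravel(), self.support_X, self.model.kernel)
        return G.T @ self.rho

    def predict(self, X: np.ndarray, standardized: bool = False) -> np.ndarray:
        f = self.decision_function(X, standardized=standardized)
        return np.where(f >= 0, 1.0, -1.0)

    def linear_weights(self) -> np.ndarray:
        """Primal weight vector (linear kernel only)."""
        if self.model.kernel.kind != "linear":
            raise ValueError("primal weights only defined for the linear kernel")
        return self.support_X.T @ self.rho

    def summary(self) -> pd.DataFrame:
        d = self.model.data
        acc = float(np.mean(self.predict(d.X)[d.certain] == d.y[d.certain])) if d.certain.any() else np.nan
        rows = {
            "n_samples": d.X.shape[0],
            "n_uncertain": int((~d.certain).sum()),
            "n_support": int(self.alpha.size),
            "kernel": self.model.kernel.kind,
            "sigma": self.model.kernel.sigma if self.model.kernel.kind == "gaussian" else np.nan,
            "C": self.model.C,
            "Ctilde": self.model.Ctilde,
            "offset_b": self.b,
            "smo_iterations": self.n_iter,
            "train_accuracy_certain": acc,
        }
        return pd.DataFrame({"value": rows})

    def to_json(self) -> str:
        return json.dumps(
            {
                "rho": self.rho.tolist(),
                "b": self.b,
                "kernel": self.model.kernel.to_dict(),
                "scaling": self.scaler.to_dict(),
                "support_points": self.support_X.tolist(),
            }
        )


def fit_psvm(data: LabeledSet, kernel: KernelSpec = KernelSpec(), C: float = 1.0,
             Ctilde: float = 1.0, standardize: bool = True) -> PSVMResults:
    """Convenience wrapper: build and fit a :class:`ProbabilisticSVM`."""
    return ProbabilisticSVM(data, kernel=kernel, C=C, Ctilde=Ctilde, standardize=standardize).fit()


def decision_value(results: PSVMResults, x: np.ndarray, standardized: bool = True) -> float:
    """Decision value of a single (standardized) point."""
    return float(results.decision_function(np.atleast_2d(x), standardized=standardized)[0])
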