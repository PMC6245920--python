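"""Kernel functions, kernel matrices and the kernel-induced Riemannian metric.

The Gaussian kernel is parameterized as ``k(x1, x2) = exp(-(1/sigma) * ||x1 - x2||^2)``,
so ``sigma`` plays the role of a squared length scale (larger sigma = smoother
decision surfaces).  The linear kernel is the plain dot product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "kernel_eval",
    "kernel_matrix",
    "kernel_gradient",
    "metric_inverse",
]

_VALID_KINDS = ("gaussian", "linear")


@dataclass(frozen=True)
class KernelSpec:
    """Specification of a positive semi-definite kernel.

    Parameters
    ----------
    kind : {"gaussian", "linear"}
        Kernel family.
    sigma : float, optional
        Scale of the Gaussian kernel, ``k(x1,x2) = exp(-(1/sigma)||x1-x2||^2)``.
        Required (and must be positive) when ``kind == "gaussian"``; ignored for
        the linear kernel.
    """

    kind: str = "gaussian"
    sigma: float | None = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected one of {_VALID_KINDS}")
        if self.kind == "gaussian":
            if self.sigma is None or not np.isfinite(self.sigma) or self.sigma <= 0:
                raise ValueError("gaussian kernel requires sigma > 0")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(kind=d["kind"], sigma=d.get("sigma"))


def kernel_eval(x1: np.ndarray, x2: np.ndarray, spec: KernelSpec) -> float:
    """Evaluate ``k(x1, x2)`` for a pair of points."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"length mismatch: {x1.shape} vs {x2.shape}")
    if spec.kind == "gaussian":
        d2 = float(np.sum((x1 - x2) ** 2))
        return float(np.exp(-d2 / spec.sigma))
    return float(x1 @ x2)


def kernel_matrix(X: np.ndarray, Y: np.ndarray | None = None, spec: KernelSpec = KernelSpec()) -> np.ndarray:
    """Kernel matrix between the rows of ``X`` and the rows of ``Y`` (default ``X``).

    Returns an ``(n_x, n_y)`` array.  For ``Y is None`` the result is symmetric
    positive semi-definite up to round-off.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.kind == "gaussian":
        d2 = cdist(X, Y, metric="sqeuclidean")
        return np.exp(-d2 / spec.sigma)
    return X @ Y.T


def kernel_gradient(x0: np.ndarray, X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gradient of ``k(x, x_i)`` with respect to ``x`` evaluated at ``x0``.

    Returns an ``(n, p)`` array whose row ``i`` is ``D_a k(x0, x_i)``.  For the
    Gaussian kernel ``D_a k(x0, x_i) = (2/sigma) (x_i^a - x0^a) k(x0, x_i)``;
    for the linear kernel the gradient is simply ``x_i``.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if spec.kind == "gaussian":
        k = kernel_matrix(x0[None, :], X, spec).ravel()  # (n,)
        return (2.0 / spec.sigma) * (X - x0[None, :]) * k[:, None]
    return X.copy()


def metric_inverse(spec: KernelSpec, p: int) -> np.ndarray:
    """Inverse ``g^{ab}`` of the kernel-induced Riemannian metric on input space.

    The metric tensor is the second cross-derivative of the kernel at coincident
    points, ``g_ab = d^2 k(x, y) / dx^a dy^b |_{y=x}``.  For the Gaussian kernel
    as parameterized here this is ``(2/sigma) I`` independent of position, hence
    the inverse is ``(sigma/2) I``; for the linear kernel both are the identity.
    """
    if spec.kind == "gaussian":
        return (spec.sigma / 2.0) * np.eye(p)
    if spec.kind == "linear":
        return np.eye(p)
    raise ValueError(f"metric not available for kernel kind {spec.kind!r}")
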