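"""KPCA embedding and maximum-growth (tangent field) variable ranking.

Kernel PCA embeds the training sample into the leading axes of the centered
kernel matrix.  Any smooth function f of the inputs — a coordinate, or the
SVM decision function — defines a *maximum-growth* direction at each sample:
the gradient of f under the kernel-induced Riemannian metric, pushed through
the embedding.  Projected onto the two leading axes these directions form a
tangent vector field, one arrow per sample.

A variable whose field consistently aligns (angle near 0) or anti-aligns
(angle near pi) with a reference field — the SVM prediction treated as an
extra variable, or the projected gradient of the decision function itself —
is associated with the outcome; a variable whose angles scatter is noise.
Recursive elimination removes, at each step, the variable whose mean angle is
closest to the median of all mean angles (the least distinguishable one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kernels import KernelSpec, kernel_gradient, kernel_matrix, metric_inverse
from .psvm import LabeledSet, PSVMResults
from .preprocessing import standardize
from .rfe import RFEResults, _BaseRFE
from .survival import SurvivalDataset

__all__ = [
    "KPCAEmbedding",
    "GrowthField",
    "kpca_fit",
    "project_point",
    "growth_direction",
    "coordinate_growth_field",
    "decision_function_growth_field",
    "angle",
    "field_angles",
    "MaxGrowthRFE",
    "rank_maxgrowth",
]


@dataclass
class KPCAEmbedding:
    """Kernel PCA of a training sample.

    ``Vtilde`` holds the eigenvectors of the centered kernel matrix scaled by
    ``1/sqrt(eigenvalue)`` so each feature-space axis has unit norm; sample
    scores are then ``K_centered @ Vtilde``.  ``projector`` is the matrix that
    maps a centered kernel row to scores, precomputed for reuse.
    """

    X: np.ndarray
    kernel: KernelSpec
    K: np.ndarray
    Vtilde: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    r: int
    projector: np.ndarray  # (I - 11'/n) Vtilde
    row_mean: np.ndarray   # (1/n) 1' K


def kpca_fit(X: np.ndarray, kernel: KernelSpec = KernelSpec(), r: int = 2) -> KPCAEmbedding:
    """Eigendecompose the centered kernel matrix and retain ``r`` leading axes.

    If fewer than ``r`` eigenvalues are numerically positive, ``r`` is reduced
    with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    K = kernel_matrix(X, spec=kernel)
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K @ J
    Kc = (Kc + Kc.T) / 2
    evals, evecs = np.linalg.eigh(Kc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals[0], 0.0) * 1e-10
    n_pos = int(pos.sum())
    if n_pos < r:
        warnings.warn(f"kernel matrix rank {n_pos} below requested r={r}; reducing")
        r = max(n_pos, 1)
    evals_r = evals[:r]
    U = evecs[:, :r]
    # orient each axis so its largest-magnitude loading is positive
    for k in range(r):
        idx = np.argmax(np.abs(U[:, k]))
        if U[idx, k] < 0:
            U[:, k] = -U[:, k]
    Vtilde = U / np.sqrt(np.maximum(evals_r, 1e-300))
    scores = Kc @ Vtilde
    return KPCAEmbedding(
        X=X, kernel=kernel, K=K, Vtilde=Vtilde, scores=scores,
        eigenvalues=evals_r, r=r, projector=J @ Vtilde, row_mean=K.mean(axis=0),
    )


def project_point(emb: KPCAEmbedding, x: np.ndarray) -> np.ndarray:
    """Project a new (standardized) input point onto the KPCA axes."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != emb.X.shape[1]:
        raise ValueError("dimension mismatch with the embedding")
    Z = kernel_matrix(x[None, :], emb.X, emb.kernel).ravel()
    return (Z - emb.row_mean) @ emb.projector


@dataclass
class GrowthField:
    """Tangent vectors of a maximum-growth direction, one per training sample."""

    label: str
    vectors: np.ndarray  # (n, r)

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def normalized(self, length: float = 1.0) -> np.ndarray:
        """Unit-length display copies (zero vectors stay zero)."""
        nrm = self.norms
        safe = np.where(nrm < 1e-12, 1.0, nrm)
        return length * self.vectors / safe[:, None]


def growth_direction(emb: KPCAEmbedding, partials: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Project the metric gradient with components ``D_b f`` at ``x0``.

    The input-space velocity is ``dx/dt = G^{-1} grad f``; the induced kernel
    row velocity is ``dZ_i/dt = sum_a D_a k(x0, x_i) dx^a/dt`` and its
    centered projection onto the KPCA axes is returned.
    """
    partials = np.asarray(partials, dtype=float).ravel()
    x0 = np.asarray(x0, dtype=float).ravel()
    p = emb.X.shape[1]
    if partials.shape[0] != p or x0.shape[0] != p:
        raise ValueError("dimension mismatch")
    Ginv = metric_inverse(emb.kernel, p)
    dxdt = Ginv @ partials
    if not np.any(dxdt):
        return np.zeros(emb.r)
    G = kernel_gradient(x0, emb.X, emb.kernel)  # (n, p)
    dZ = G @ dxdt
    return dZ @ emb.projector


def coordinate_growth_field(emb: KPCAEmbedding, variable: int,
                            label: str | None = None) -> GrowthField:
    """Growth field of the coordinate function f(x) = x^a at every sample."""
    p = emb.X.shape[1]
    if not 0 <= variable < p:
        raise ValueError(f"variable index {variable} out of range")
    spec = emb.kernel
    if spec.kind == "gaussian":
        # dx/dt = (sigma/2) e_a ; dZ_i/dt at anchor m = (x_i^a - x_m^a) K_mi
        col = emb.X[:, variable]
        M = (col[None, :] - col[:, None]) * emb.K
        vectors = M @ emb.projector
    else:
        row = emb.X[:, variable] @ emb.projector
        vectors = np.tile(row, (emb.X.shape[0], 1))
    return GrowthField(label=label or f"V{variable + 1}", vectors=vectors)


def decision_function_growth_field(emb: KPCAEmbedding, model: PSVMResults) -> GrowthField:
    """Growth field of the SVM decision function f(x) = sum rho_i k(x_i,x) + b."""
    if model.kernel.kind != emb.kernel.kind or (
        model.kernel.kind == "gaussian" and not np.isclose(model.kernel.sigma, emb.kernel.sigma)
    ):
        raise ValueError("model and embedding must share the kernel")
    n = emb.X.shape[0]
    vectors = np.empty((n, emb.r))
    for m in range(n):
        partials = model.decision_gradient(emb.X[m])
        vectors[m] = growth_direction(emb, partials, emb.X[m])
    return GrowthField(label="decision", vectors=vectors)


def angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in [0, pi]; 0 = aligned, pi = opposite."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("angle undefined for zero-length vectors")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.arccos(c))


def field_angles(field: GrowthField, reference: GrowthField) -> np.ndarray:
    """Per-sample angles between two fields; NaN where either vector vanishes."""
    A, B = field.vectors, reference.vectors
    na, nb = np.linalg.norm(A, axis=1), np.linalg.norm(B, axis=1)
    valid = (na >= 1e-12) & (nb >= 1e-12)
    out = np.full(A.shape[0], np.nan)
    dots = np.einsum("ij,ij->i", A, B)
    out[valid] = np.arccos(np.clip(dots[valid] / (na[valid] * nb[valid]), -1.0, 1.0))
    return out


def _mean_angle(field: GrowthField, reference: GrowthField) -> float:
    ang = field_angles(field, reference)
    ok = ~np.isnan(ang)
    if not ok.any():
        return np.nan
    return float(np.mean(ang[ok]))


class MaxGrowthRFE(_BaseRFE):
    """RFE by angle between variable growth fields and an SVM reference.

    ``variant="prediction"`` embeds the data augmented with the standardized
    decision values as an extra (non-candidate) variable and uses that
    column's field as the reference; ``variant="function"`` embeds the data
    alone and uses the projected gradient of the decision function.  Each
    iteration removes the variable whose mean angle is *closest to the median*
    of all surviving variables' mean angles — the least distinguishable from
    the bulk (ties broken toward the lowest index).
    """

    def __init__(self, data: LabeledSet | SurvivalDataset, kernel: KernelSpec = KernelSpec(),
                 C: float = 1.0, Ctilde: float = 1.0, variant: str = "prediction",
                 r: int = 2, min_variables: int = 1):
        if variant not in ("prediction", "function"):
            raise ValueError("variant must be 'prediction' or 'function'")
        super().__init__(data, kernel=kernel, C=C, Ctilde=Ctilde, min_variables=min_variables)
        self.variant = variant
        self.r = r
        self.method = f"maxgrowth-{variant}"
        self._last_fields: dict | None = None

    def _mean_angles(self, model: PSVMResults, sub: LabeledSet) -> np.ndarray:
        p = sub.X.shape[1]
        if self.variant == "prediction":
            pred = model.decision_function(sub.X, standardized=True)
            pred_std, _ = standardize(pred[:, None])
            X_aug = np.hstack([sub.X, pred_std])
            emb = kpca_fit(X_aug, kernel=self.kernel, r=self.r)
            reference = coordinate_growth_field(emb, p, label="reference")
        else:
            emb = kpca_fit(sub.X, kernel=self.kernel, r=self.r)
            reference = decision_function_growth_field(emb, model)
        fields = [coordinate_growth_field(emb, j, label=sub.names[j]) for j in range(p)]
        self._last_fields = {
            "embedding": emb,
            "reference": reference,
            "fields": fields,
            "names": list(sub.names),
        }
        return np.array([_mean_angle(f, reference) for f in fields])

    def _criterion(self, model: PSVMResults, sub: LabeledSet) -> np.ndarray:
        mean_angles = self._mean_angles(model, sub)
        med = np.nanmedian(mean_angles)
        dist = np.abs(mean_angles - med)
        # NaN mean angle (all vectors degenerate) = maximally uninformative
        return np.where(np.isnan(dist), -1.0, dist)

    def fit(self) -> RFEResults:
        res = super().fit()
        res.extras["last_fields"] = self._last_fields
        return res


def rank_maxgrowth(data: LabeledSet | SurvivalDataset, kernel: KernelSpec = KernelSpec(),
                   C: float = 1.0, Ctilde: float = 1.0,
                   variant: str = "prediction") -> RFEResults:
    """One-call maximum-growth ranking; see :class:`MaxGrowthRFE`."""
    return MaxGrowthRFE(data, kernel=kernel, C=C, Ctilde=Ctilde, variant=variant).fit()
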