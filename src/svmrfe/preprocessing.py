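"""Column standardization with reusable centers/scales."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Standardizer", "standardize"]


@dataclass
class Standardizer:
    """Per-column centering and scaling, reusable on new points.

    Constant columns get scale 1 so they map to exact zeros instead of NaN;
    they carry no information and are legitimately rankable as irrelevant.
    """

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.isnan(X).any():
            raise ValueError("missing values in predictor matrix")
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        scale = np.where(scale < 1e-12, 1.0, scale)
        return cls(center=center, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.center) / self.scale

    def transform_vector(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.scale

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(center=np.asarray(d["center"], float), scale=np.asarray(d["scale"], float))


def standardize(X: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Center and scale each column to mean 0, sd 1 (sd taken with ddof=1).

    Returns the transformed matrix and the fitted :class:`Standardizer`.
    """
    scaler = Standardizer.fit(X)
    return scaler.transform(X), scaler
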