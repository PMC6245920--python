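"""Landmark encoding of right-censored time-to-event data for the SVM.

A survival sample is mapped to a binary class by its status at a landmark
(end-of-follow-up) time ``tau``: subjects with an event before ``tau`` are
certain events (class -1), subjects still under observation at ``tau`` are
certain non-events (class +1), and subjects censored before ``tau`` get an
uncertain label with membership probability equal to their conditional
probability of surviving to ``tau``, ``pi = S(tau) / S(c)``, taken from the
Kaplan-Meier curve of the full training sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .psvm import LabeledSet

__all__ = ["SurvivalDataset", "KMCurve", "km_estimate", "encode_landmark", "read_survival_csv"]


@dataclass
class SurvivalDataset:
    """Right-censored survival data with a predictor matrix.

    ``status`` uses 1 = event, 0 = censored.  ``tau`` is the landmark /
    administrative end-of-follow-up time used for classification encoding.
    """

    X: np.ndarray
    time: np.ndarray
    status: np.ndarray
    tau: float
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.status = np.asarray(self.status, dtype=int).ravel()
        if np.isnan(self.time).any() or np.isnan(self.X).any():
            raise ValueError("missing values not allowed")
        if (self.time < 0).any():
            raise ValueError("negative follow-up times")
        if not np.all(np.isin(self.status, (0, 1))):
            raise ValueError("status must be 0 (censored) or 1 (event)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not self.names:
            self.names = [f"V{j + 1}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "status", self.status)
        df.insert(0, "time", self.time)
        return df


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve as a right-continuous step function."""

    event_times: np.ndarray
    survival: np.ndarray

    def __call__(self, t: float) -> float:
        """Survival probability S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time: np.ndarray, status: np.ndarray) -> KMCurve:
    """Product-limit survival estimate (via lifelines).

    The curve drops by a factor ``1 - d_i/n_i`` at each distinct event time.
    """
    time = np.asarray(time, dtype=float).ravel()
    status = np.asarray(status, dtype=int).ravel()
    if time.size == 0:
        raise ValueError("need at least one observation")
    if (time < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=status)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return KMCurve(event_times=t[keep], survival=s[keep])


def encode_landmark(data: SurvivalDataset) -> LabeledSet:
    """Convert a survival dataset to labels and membership probabilities.

    Uses event = -1 / non-event = +1 and attaches ``pi = S(tau)/S(c)`` to
    samples censored at ``c < tau``.
    """
    tau = data.tau
    event_before = (data.status == 1) & (data.time <= tau)
    at_risk = data.time >= tau
    censored_early = (data.status == 0) & (data.time < tau)

    if not event_before.any():
        raise ValueError("no events observed before the landmark time; encoding degenerates")

    curve = km_estimate(data.time, data.status)
    s_tau = curve(tau)

    y = np.ones(data.n)
    pi = np.ones(data.n)
    y[event_before] = -1.0
    pi[event_before] = 0.0
    for i in np.flatnonzero(censored_early):
        s_c = curve(data.time[i])
        if s_c <= 0:
            raise ValueError("survival estimate vanished before a censored observation")
        pi[i] = min(s_tau / s_c, 1.0)
        y[i] = 1.0 if pi[i] >= 0.5 else -1.0
    return LabeledSet(X=data.X, y=y, pi=pi, names=list(data.names))


def read_survival_csv(path: str | Path, tau: float, time_col: str = "time",
                      status_col: str = "status") -> SurvivalDataset:
    """Read a delimited survival table (1 = event, 0 = censored).

    All columns other than ``time_col``/``status_col`` are treated as numeric
    predictors; their names are preserved into rank reports.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    pred = df.drop(columns=[time_col, status_col])
    return SurvivalDataset(
        X=pred.to_numpy(dtype=float),
        time=df[time_col].to_numpy(dtype=float),
        status=df[status_col].to_numpy(dtype=int),
        tau=tau,
        names=list(pred.columns),
    )
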