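"""Comparing ranking methods: rank summaries, Spearman agreement,
concordance-by-rank, and the Cox likelihood-share RFE comparator."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy.stats import spearmanr

from .rfe import RankResult, RFEResults
from .survival import SurvivalDataset

__all__ = [
    "summarize_ranks",
    "spearman_rank_corr",
    "harrell_c",
    "concordance_by_rank",
    "cox_rfe_rank",
    "CoxRFE",
]


def summarize_ranks(results: list[RankResult | RFEResults | dict[str, int]]) -> pd.DataFrame:
    """Mean and standard deviation of each variable's rank over replicates.

    All results must cover the same variable set.  Output rows are ordered by
    variable (column) index as in the input data.
    """
    if not results:
        raise ValueError("no results to summarize")
    dicts = []
    for r in results:
        if isinstance(r, RFEResults):
            dicts.append(r.ranks)
        elif isinstance(r, RankResult):
            dicts.append(r.ranks)
        else:
            dicts.append(dict(r))
    names = list(dicts[0].keys())
    for d in dicts[1:]:
        if set(d.keys()) != set(names):
            raise ValueError("inconsistent variable sets across replicates")
    M = np.array([[d[n] for n in names] for d in dicts], dtype=float)
    return pd.DataFrame(
        {
            "variable": names,
            "mean_rank": M.mean(axis=0),
            "sd_rank": M.std(axis=0, ddof=1) if M.shape[0] > 1 else np.zeros(len(names)),
            "n_replicates": M.shape[0],
        }
    )


def spearman_rank_corr(r1, r2) -> float:
    """Spearman correlation between two rankings of the same variables.

    Accepts rank dicts (aligned by variable name) or plain vectors.
    """
    if isinstance(r1, dict) and isinstance(r2, dict):
        if set(r1) != set(r2):
            raise ValueError("rankings cover different variable sets")
        names = sorted(r1)
        a = np.array([r1[n] for n in names], float)
        b = np.array([r2[n] for n in names], float)
    else:
        a = np.asarray(r1, float).ravel()
        b = np.asarray(r2, float).ravel()
        if a.shape != b.shape:
            raise ValueError("length mismatch")
    return float(spearmanr(a, b).statistic)


def harrell_c(risk: np.ndarray, time: np.ndarray, status: np.ndarray) -> float:
    """Harrell's concordance of a risk score against right-censored times.

    Fraction of comparable pairs (the shorter time has an event) in which the
    higher risk score has the shorter time; score ties count 1/2.  Implemented
    via lifelines' concordance index, which expects higher = longer survival,
    hence the sign flip.
    """
    risk = np.asarray(risk, float).ravel()
    return float(concordance_index(np.asarray(time, float), -risk, np.asarray(status, int)))


def _fit_cox(df: pd.DataFrame, cols: list[str], penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[["time", "status", *cols]], duration_col="time", event_col="status")
    return cph


def _cox_loglik(df: pd.DataFrame, cols: list[str]) -> tuple[float, float, CoxPHFitter]:
    """(log-likelihood, null log-likelihood, fitted model) with ridge fallback."""
    try:
        cph = _fit_cox(df, cols)
    except Exception:
        cph = _fit_cox(df, cols, penalizer=0.1)
    ll = float(cph.log_likelihood_)
    lr = cph.log_likelihood_ratio_test().test_statistic
    ll_null = ll - float(lr) / 2.0
    return ll, ll_null, cph

def concordance_by_rank(rank: RankResult | RFEResults, data: SurvivalDataset,
                        cumulative: bool = False) -> pd.DataFrame:
    """Harrell's C of the variable occupying each rank position.

    Default (per-rank) mode fits a univariate proportional-hazards model for
    the variable at each rank and scores its linear predictor; with
    ``cumulative=True`` the top-k variables enter jointly at position k.
    """
    ranks = rank.ranks if not isinstance(rank, dict) else rank
    if set(ranks) - set(data.names):
        raise ValueError("rank variables not present in dataset")
    df = data.to_frame()
    ordered = [n for n, _ in sorted(ranks.items(), key=lambda kv: kv[1])]
    rows = []
    for pos, name in enumerate(ordered, start=1):
        cols = ordered[:pos] if cumulative else [name]
        try:
            _, _, cph = _cox_loglik(df, cols)
            risk = cph.predict_partial_hazard(df).to_numpy(dtype=float)
            c = harrell_c(np.log(risk), data.time, data.status)
        except Exception:
            # last resort: orient the raw variable by a penalized coefficient sign
            cph = _fit_cox(df, cols, penalizer=1.0)
            sign = np.sign(cph.params_.get(name, 1.0)) or 1.0
            c = harrell_c(sign * df[name].to_numpy(), data.time, data.status)
        rows.append({"rank": pos, "variable": name, "c_statistic": c})
    return pd.DataFrame(rows)


def cox_rfe_rank(data: SurvivalDataset, min_variables: int = 1) -> RFEResults:
    """Cox-model RFE by smallest share of explainable partial log-likelihood.

    At each iteration the share of variable v is
    ``[logL(model) - logL(model without v)] / [logL(model) - logL(null))]``;
    the variable with the smallest share is removed (ties toward the lowest
    column index).  Non-convergent fits fall back to a ridge penalty.
    """
    df = data.to_frame()
    surviving = list(data.names)
    ranks: dict[str, int] = {}
    trace: list[dict] = []
    iteration = 0
    while len(surviving) > max(min_variables, 1):
        iteration += 1
        ll_full, ll_null, _ = _cox_loglik(df, surviving)
        denom = ll_full - ll_null
        shares = np.empty(len(surviving))
        for i, v in enumerate(surviving):
            rest = [w for w in surviving if w != v]
            if rest:
                ll_minus, _, _ = _cox_loglik(df, rest)
            else:
                ll_minus = ll_null
            shares[i] = (ll_full - ll_minus) / denom if abs(denom) > 1e-12 else 0.0
        drop = int(np.argmin(shares))
        removed = surviving[drop]
        ranks[removed] = len(surviving)
        trace.append(
            {
                "iteration": iteration,
                "removed": removed,
                "criterion": {surviving[i]: float(shares[i]) for i in range(len(surviving))},
            }
        )
        surviving.pop(drop)
    order = {n: i for i, n in enumerate(data.names)}
    for r, v in enumerate(sorted(surviving, key=order.get)):
        ranks[v] = r + 1
    return RFEResults(RankResult(ranks=ranks, trace=trace), method="cox")


class CoxRFE:
    """Model-style wrapper around :func:`cox_rfe_rank`."""

    method = "cox"

    def __init__(self, data: SurvivalDataset, min_variables: int = 1):
        self.data = data
        self.min_variables = min_variables

    def fit(self) -> RFEResults:
        return cox_rfe_rank(self.data, min_variables=self.min_variables)
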