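"""Loaders for the public PBC and Lung survival benchmarks.

The tables are exported at run time from the R ``survival`` package (via
``Rscript``), so no data files are bundled.  Analysis subsets are the
complete cases, statuses are recoded to 1 = death, 0 = censored, and the
landmark is the study's end of follow-up (2771 days for PBC, 420 for Lung).
A user-supplied CSV can always be read instead with
:func:`svmrfe.survival.read_survival_csv`.
"""

from __future__ import annotations

import io
import shutil
import subprocess

import pandas as pd

from .survival import SurvivalDataset

__all__ = ["load_pbc", "load_lung"]

PBC_TAU = 2771.0
LUNG_TAU = 420.0


def _r_export(code: str) -> pd.DataFrame:
    """Run an R snippet that writes a CSV to stdout and parse it."""
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript not found; supply the dataset as a CSV instead")
    proc = subprocess.run(
        ["Rscript", "--vanilla", "-e", code],
        capture_output=True, text=True, timeout=120,
    )
    if proc.returncode != 0:
        raise RuntimeError(f"R export failed: {proc.stderr.strip()[:500]}")
    return pd.read_csv(io.StringIO(proc.stdout))


def load_pbc() -> SurvivalDataset:
    """Mayo Clinic primary biliary cirrhosis trial (complete cases).

    Predictors: the 17 clinical covariates (treatment, demographics, labs,
    histologic stage); sex is coded 1 = female, 0 = male.
    """
    df = _r_export(
        "suppressMessages(library(survival)); d <- pbc[complete.cases(pbc),];"
        "d$sex <- as.integer(d$sex=='f');"
        "write.csv(d, stdout(), row.names=FALSE)"
    )
    df = df.drop(columns=[c for c in ("id",) if c in df.columns])
    status = (df.pop("status") == 2).astype(int)
    time = df.pop("time").astype(float)
    return SurvivalDataset(
        X=df.to_numpy(dtype=float), time=time.to_numpy(), status=status.to_numpy(),
        tau=PBC_TAU, names=list(df.columns),
    )


def load_lung(drop_institution: bool = True) -> SurvivalDataset:
    """NCCTG advanced lung cancer cohort (complete cases).

    ``inst`` (institution code) is dropped by default as a non-clinical
    identifier.
    """
    df = _r_export(
        "suppressMessages(library(survival)); d <- survival::lung;"
        "d <- d[complete.cases(d),];"
        "write.csv(d, stdout(), row.names=FALSE)"
    )
    if drop_institution and "inst" in df.columns:
        df = df.drop(columns=["inst"])
    status = (df.pop("status") == 2).astype(int)
    time = df.pop("time").astype(float)
    return SurvivalDataset(
        X=df.to_numpy(dtype=float), time=time.to_numpy(), status=status.to_numpy(),
        tau=LUNG_TAU, names=list(df.columns),
    )
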