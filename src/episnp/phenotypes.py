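"""Feed-efficiency phenotype derivation and extreme-group assignment.

FCR (feed conversion ratio) = feed consumed / weight gain; high FCR means an
inefficient animal.  RFI (residual feed intake) is the residual of an OLS
regression of observed daily feed intake on production covariates.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LFE = "LFE"  # low feed efficiency  = high FCR
HFE = "HFE"  # high feed efficiency = low FCR
MID = "MID"

REQUIRED_COLUMNS = ("sample_id", "fc", "dw", "dfi")


def compute_fcr(fc: float | np.ndarray, dw: float | np.ndarray) -> float | np.ndarray:
    """Feed conversion ratio: feed consumed per unit of weight gained."""
    dw_arr = np.asarray(dw, dtype=float)
    if np.any(dw_arr <= 0):
        raise ValueError("delta weight must be positive to define FCR")
    out = np.asarray(fc, dtype=float) / dw_arr
    return float(out) if out.ndim == 0 else out


def compute_rfi(
    table: pd.DataFrame, predictors: Sequence[str] = ("dw_per_day", "initial_weight")
) -> np.ndarray:
    """Residual feed intake: OLS residual of DFI on predictors (+ intercept).

    Residuals sum to zero by construction.  Raises on a rank-deficient
    predictor matrix, naming the deficiency.
    """
    y = table["dfi"].to_numpy(dtype=float)
    cols = [c for c in predictors if c in table.columns]
    missing = set(predictors) - set(cols)
    if missing:
        raise KeyError(f"predictor column(s) not in table: {sorted(missing)}")
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in cols]
    )
    if len(y) < X.shape[1] + 1:
        raise ValueError(f"need >= {X.shape[1] + 1} samples for {len(cols)} predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear predictor matrix: rank {rank} < {X.shape[1]} columns "
            f"(intercept + {list(cols)})"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def assign_efficiency_groups(
    fcr: Sequence[float] | np.ndarray,
    n_per_group: int,
    sample_ids: Sequence[str] | None = None,
) -> list[str]:
    """Label the FCR extremes as LFE (high FCR) and HFE (low FCR).

    Seeds each group with the samples beyond one standard deviation from the
    mean, then fills to exactly ``n_per_group`` by extremity; ties are
    resolved by sample_id order so the assignment is deterministic.
    """
    fcr = np.asarray(fcr, dtype=float)
    n = fcr.size
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if n_per_group > n // 2:
        raise ValueError(f"n_per_group={n_per_group} exceeds floor(n/2)={n // 2}")
    mean, sd = float(np.mean(fcr)), float(np.std(fcr, ddof=1)) if n > 1 else 0.0
    if sd == 0:
        warnings.warn("degenerate FCR vector (zero variance); using sample_id order")
    desc = sorted(range(n), key=lambda i: (-fcr[i], sample_ids[i]))
    asc = sorted(range(n), key=lambda i: (fcr[i], sample_ids[i]))
    labels = [MID] * n
    for i in desc[:n_per_group]:  # highest FCR -> least efficient
        labels[i] = LFE
    taken = 0  # ties spanning both cutoffs: LFE (assigned first) wins the tie
    for i in asc:
        if taken == n_per_group:
            break
        if labels[i] == MID:
            labels[i] = HFE
            taken += 1
    return labels


def derive_phenotypes(
    table: pd.DataFrame,
    n_per_group: int | None = None,
    rfi_predictors: Sequence[str] = ("dw_per_day", "initial_weight"),
    test_days_column: str = "test_days",
) -> pd.DataFrame:
    """Add fcr, dw_per_day, rfi and (optionally) group columns to a table."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"phenotype table missing required column {col!r}")
    out = table.copy()
    out["fcr"] = compute_fcr(out["fc"].to_numpy(), out["dw"].to_numpy())
    if "dw_per_day" not in out.columns:
        days = (
            out[test_days_column].to_numpy(dtype=float)
            if test_days_column in out.columns
            else np.full(len(out), 60.0)
        )
        out["dw_per_day"] = out["dw"].to_numpy(dtype=float) / days
    preds = [c for c in rfi_predictors if c in out.columns]
    if not preds:
        preds = []
    out["rfi"] = compute_rfi(out, predictors=preds)
    if n_per_group is not None:
        out["group"] = assign_efficiency_groups(
            out["fcr"].to_numpy(), n_per_group, list(out["sample_id"])
        )
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in tbl.columns:
            raise KeyError(f"{path}: missing required column {col!r}")
    return tbl


def write_groups(table: pd.DataFrame, path: str | Path) -> None:
    table[["sample_id", "group"]].to_csv(path, sep="\t", index=False)
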