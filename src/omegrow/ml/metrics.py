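"""Regression performance metrics: R², RMSE, EVS, MAE.

Implemented directly from their definitions:

    R²   = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²
    RMSE = sqrt(mean (yᵢ − ŷᵢ)²)
    EVS  = 1 − var(y − ŷ) / var(y)
    MAE  = mean |yᵢ − ŷᵢ|
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Metrics", "compute_metrics"]


@dataclass(frozen=True)
class Metrics:
    r2: float
    rmse: float
    evs: float
    mae: float
    n: int
    degenerate: bool = False  # y_true had zero variance: r2/evs are undefined

    def as_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "evs": self.evs,
            "mae": self.mae, "n": self.n,
        }


def compute_metrics(y_true, y_pred) -> Metrics:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = y_true.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    degenerate = ss_tot == 0.0
    if degenerate:
        r2 = evs = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        evs = 1.0 - float(np.var(resid)) / float(np.var(y_true))
    return Metrics(r2=r2, rmse=rmse, evs=evs, mae=mae, n=n, degenerate=degenerate)
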