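"""Regression metrics: MAE, RMSE, MAPE and the coefficient of determination.

MAPE needs care when true densities can be near zero: the relative error is
computed against ``max(|y|, floor)`` with a documented floor (default 1e-6),
so zero-density samples contribute a large but finite term instead of a
division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsRecord", "evaluate"]

MAPE_FLOOR = 1e-6


@dataclass
class MetricsRecord:
    mae: float
    rmse: float
    mape: float       # percent
    r2: float
    n: int
    y_mean: float

    def __post_init__(self):
        # MAE <= RMSE by Cauchy-Schwarz; tolerate float rounding only
        if self.mae > self.rmse + 1e-9:
            raise ValueError("internal error: MAE exceeds RMSE")

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "mape": self.mape,
                "r2": self.r2, "n": self.n, "y_mean": self.y_mean}

    def __str__(self):
        return (f"MAE={self.mae:.4f}  RMSE={self.rmse:.4f}  "
                f"MAPE={self.mape:.1f}%  R2={self.r2:.4f}  (n={self.n})")


def evaluate(y_true, y_pred, mape_floor: float = MAPE_FLOOR) -> MetricsRecord:
    """Compute the four regression metrics for a prediction set."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    n = y_true.size
    if n < 2:
        raise ValueError("need at least two samples")
    err = y_true - y_pred
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: all true values identical")
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mape = float(100.0 * np.mean(np.abs(err)
                                 / np.maximum(np.abs(y_true), mape_floor)))
    r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    return MetricsRecord(mae=mae, rmse=rmse, mape=mape, r2=r2, n=int(n),
                         y_mean=float(y_true.mean()))
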