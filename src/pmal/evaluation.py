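"""Regression metrics, NLL traces and mean ± sd aggregation across runs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score

__all__ = ["rmse", "r2", "nll_trace", "aggregate_report", "MetricsReport"]


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(f"need equal-length 1-d vectors, got {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty vectors")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("inputs must be finite")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(mean_squared_error(y_true, y_pred)))


def r2(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative for
    predictions worse than the mean.  Undefined for constant y_true."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 2 or np.ptp(y_true) == 0:
        raise ValueError("r2 is undefined for constant or singleton y_true")
    return float(r2_score(y_true, y_pred))


def nll_trace(model) -> np.ndarray:
    """The per-epoch negative-log-likelihood trace recorded during the last
    training run (empty when the model has not been trained)."""
    return np.asarray(getattr(model, "history", []), dtype=float)


@dataclass
class MetricsReport:
    """Mean ± sample sd of each metric cell across repeated runs."""

    table: pd.DataFrame  # columns: group keys + metric, mean, sd, n

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def aggregate_report(runs: pd.DataFrame,
                     group_keys: tuple[str, ...] = ("round", "task"),
                     metrics: tuple[str, ...] = ("rmse", "r2")) -> MetricsReport:
    """Aggregate per-run metric rows into mean ± sd (ddof=1; sd = 0 for a
    single run) per group cell."""
    if len(runs) == 0:
        raise ValueError("no runs to aggregate")
    keys = [k for k in group_keys if k in runs.columns]
    out_rows = []
    for group_vals, chunk in runs.groupby(list(keys)) if keys else [((), runs)]:
        if not isinstance(group_vals, tuple):
            group_vals = (group_vals,)
        for metric in metrics:
            if metric not in chunk.columns:
                continue
            vals = chunk[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            out_rows.append({
                **dict(zip(keys, group_vals)),
                "metric": metric,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            })
    return MetricsReport(pd.DataFrame(out_rows))
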