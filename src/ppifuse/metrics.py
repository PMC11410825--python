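"""Evaluation metrics and run-level statistics.

Regression-style error metrics compare continuous fused scores against the
0/1 labels; classification accuracy thresholds the scores at 0.5 (ties
count positive). Run statistics summarize repeated optimizer runs under the
minimization convention (best = min) with the sample (n-1) standard
deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np

log = logging.getLogger(__name__)

EPS = 1e-8


@dataclass
class MetricsReport:
    """Scalar error metrics for one (actual, predicted) comparison."""

    mae: float
    mare: float
    mase: float
    mse: float
    msre: float
    rae: float
    rmse: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def regression_metrics(actual, predicted) -> MetricsReport:
    """MAE, MARE, MASE, MSE, MSRE, RAE and RMSE of predictions vs actuals.

    MARE/MSRE guard zero actuals with a small epsilon; RAE normalizes by the
    deviation from the actuals' mean; MASE uses the naive one-step scale
    mean|y_i - y_{i-1}|. Degenerate denominators yield NaN with a warning.
    """
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size == 0:
        raise ValueError("metrics of empty input")
    if y.shape != yhat.shape:
        raise ValueError("actual and predicted must have equal lengths")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = math.sqrt(mse)
    mare = float(np.mean(np.abs(err) / np.maximum(np.abs(y), EPS)))
    msre = float(np.mean(err**2 / np.maximum(y**2, EPS)))
    rae_denom = float(np.sum(np.abs(y - y.mean())))
    if rae_denom == 0:
        log.warning("RAE denominator is zero; reporting NaN")
        rae = math.nan
    else:
        rae = float(np.sum(np.abs(err)) / rae_denom)
    if y.size < 2:
        log.warning("MASE needs at least 2 observations; reporting NaN")
        mase = math.nan
    else:
        scale = float(np.mean(np.abs(np.diff(y))))
        if scale == 0:
            log.warning("MASE naive scale is zero; reporting NaN")
            mase = math.nan
        else:
            mase = mae / scale
    return MetricsReport(mae=mae, mare=mare, mase=mase, mse=mse, msre=msre, rae=rae, rmse=rmse)


def classification_accuracy(labels, scores, threshold: float = 0.5) -> float:
    """Fraction of pairs where [score >= threshold] matches the 0/1 label."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("accuracy of empty input")
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal lengths")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0/1")
    predicted = (s >= threshold).astype(int)
    return float(np.mean(predicted == y))


@dataclass
class RunStatistics:
    best: float
    worst: float
    mean: float
    median: float
    std: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def run_statistics(objective_values) -> RunStatistics:
    """Best/worst/mean/median/STD over repeated runs (minimization; n-1 STD)."""
    values = np.asarray(objective_values, dtype=float)
    if values.size == 0:
        raise ValueError("statistics of empty input")
    std = 0.0 if values.size == 1 else float(np.std(values, ddof=1))
    return RunStatistics(
        best=float(values.min()),
        worst=float(values.max()),
        mean=float(values.mean()),
        median=float(np.median(values)),
        std=std,
    )
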