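"""Modified score-level fusion of the two predictor score vectors.

The two models' mean absolute percentage errors (MAPE) on a held-out
validation split determine global weights w1, w2 (normalized to sum 1); the
fused score is the elementwise convex combination FS = w1 * s_mRNN +
w2 * s_DBN, with the plain average as the baseline mode.

As written the weight formulas give the lower-MAPE model the SMALLER
weight; that literal form is the default, and ``invert=True`` swaps the
numerators so the better model dominates. MAPE here uses absolute errors
(signed relative errors can cancel to a meaningless zero) and guards zero
actuals with a small epsilon.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

MAPE_EPS = 1e-8


def mape(actual, predicted, eps: float = MAPE_EPS) -> float:
    """100 * mean(|y - yhat| / max(|y|, eps))."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size == 0:
        raise ValueError("mape of empty input")
    if y.shape != yhat.shape:
        raise ValueError("actual and predicted must have equal lengths")
    if not np.all(np.isfinite(yhat)):
        raise ValueError("predictions must be finite")
    denom = np.maximum(np.abs(y), eps)
    if np.any(np.abs(y) < eps):
        log.warning("mape: %d zero actual values guarded by eps", int((np.abs(y) < eps).sum()))
    return float(100.0 * np.mean(np.abs(y - yhat) / denom))


def fusion_weights(mape_mrnn: float, mape_dbn: float, invert: bool = False) -> tuple[float, float]:
    """MAPE-proportional weights (w1 for the mRNN, w2 for the DBN), summing to 1.

    Literal mode: w1 = mape_mrnn / (mape_dbn + mape_mrnn). ``invert=True``
    swaps the numerators so the lower-MAPE model receives the larger weight.
    Two zero MAPEs give (0.5, 0.5).
    """
    if mape_mrnn < 0 or mape_dbn < 0:
        raise ValueError("MAPE values must be non-negative")
    total = mape_mrnn + mape_dbn
    if total == 0:
        return 0.5, 0.5
    w1 = mape_mrnn / total
    w2 = mape_dbn / total
    if invert:
        w1, w2 = w2, w1
    return w1, w2


def fuse_scores(s_mrnn, s_dbn, w1: float = 0.5, w2: float = 0.5) -> np.ndarray:
    """Elementwise convex combination w1 * s_mRNN + w2 * s_DBN.

    With w1 = w2 = 0.5 this is the conventional score average. Weights must
    sum to 1 (tolerance 1e-9).
    """
    s1 = np.asarray(s_mrnn, dtype=float)
    s2 = np.asarray(s_dbn, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("score vectors must have equal lengths")
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w1 + w2}")
    return w1 * s1 + w2 * s2


def average_fusion(s_mrnn, s_dbn) -> np.ndarray:
    """Baseline unweighted score average."""
    return fuse_scores(s_mrnn, s_dbn, 0.5, 0.5)
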