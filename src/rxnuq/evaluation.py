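"""Regression metrics, error-uncertainty rank correlation, and the
selective-prediction coverage sweep.

Selective prediction rejects the most uncertain predictions: at coverage
``c`` the ``ceil(c * n)`` predictions with the smallest uncertainty score
are kept (stable sort, ties broken by original index) and MAE/RMSE are
recomputed on that subset.  A good uncertainty score makes the curve fall
as coverage decreases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

__all__ = [
    "EvalReport", "CoverageCurve",
    "regression_metrics", "spearman_error_uncertainty",
    "selective_metrics", "coverage_curve", "evaluate_predictions",
    "aggregate_over_runs", "DEFAULT_COVERAGES",
]

DEFAULT_COVERAGES = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3)


@dataclass
class EvalReport:
    mae: float
    rmse: float
    r2: float
    spearman_rho: float
    n: int


@dataclass
class CoverageCurve:
    coverages: tuple
    mae_at: tuple
    rmse_at: tuple
    kept_n: tuple


def regression_metrics(y_true, y_pred):
    """(MAE, RMSE, R^2).  R^2 uses total sum of squares about the mean of
    ``y_true``; a constant ``y_true`` leaves it undefined (NaN, with a
    warning)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-d arrays")
    if y_true.size < 2:
        raise ValueError("need at least 2 points")
    mae = float(mean_absolute_error(y_true, y_pred))
    rmse = float(math.sqrt(mean_squared_error(y_true, y_pred)))
    if np.all(y_true == y_true[0]):
        warnings.warn("constant y_true: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = float(r2_score(y_true, y_pred))
    return mae, rmse, r2


def spearman_error_uncertainty(abs_errors, uncertainty_scores) -> float:
    """Spearman rank correlation between absolute prediction errors and
    uncertainty scores (average ranks for ties).  Positive values mean the
    score ranks erroneous predictions as uncertain."""
    e = np.asarray(abs_errors, dtype=float)
    u = np.asarray(uncertainty_scores, dtype=float)
    if e.shape != u.shape or e.size < 2:
        raise ValueError("need equal-length lists with n >= 2")
    if np.all(e == e[0]) or np.all(u == u[0]):
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan")
    return float(sps.spearmanr(e, u).statistic)


def _keep_indices(uncertainty_scores, coverage: float):
    n = len(uncertainty_scores)
    if not (0.0 < coverage <= 1.0):
        raise ValueError(f"coverage {coverage} outside (0, 1]")
    k = math.ceil(coverage * n)
    order = np.argsort(uncertainty_scores, kind="stable")
    return np.sort(order[:k])


def selective_metrics(y_true, y_pred, uncertainty_scores, coverage: float):
    """MAE/RMSE on the ``ceil(coverage * n)`` least-uncertain predictions.
    Returns ``(mae, rmse, kept_n)``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    u = np.asarray(uncertainty_scores, dtype=float)
    if not (y_true.shape == y_pred.shape == u.shape):
        raise ValueError("inputs must have equal length")
    keep = _keep_indices(u, coverage)
    err = y_true[keep] - y_pred[keep]
    mae = float(np.mean(np.abs(err)))
    rmse = float(math.sqrt(np.mean(err ** 2)))
    return mae, rmse, int(keep.size)


def coverage_curve(y_true, y_pred, uncertainty_scores,
                   coverages=DEFAULT_COVERAGES) -> CoverageCurve:
    """Selective-prediction sweep over a grid of coverages (default 100%
    down to 30%)."""
    maes, rmses, ns = [], [], []
    for c in coverages:
        mae, rmse, kept = selective_metrics(y_true, y_pred,
                                            uncertainty_scores, c)
        maes.append(mae)
        rmses.append(rmse)
        ns.append(kept)
    return CoverageCurve(tuple(coverages), tuple(maes), tuple(rmses), tuple(ns))


def evaluate_predictions(y_true, y_pred, uncertainty_scores) -> EvalReport:
    """Full report: regression metrics plus the error-uncertainty rank
    correlation."""
    mae, rmse, r2 = regression_metrics(y_true, y_pred)
    rho = spearman_error_uncertainty(
        np.abs(np.asarray(y_true, float) - np.asarray(y_pred, float)),
        uncertainty_scores)
    return EvalReport(mae=mae, rmse=rmse, r2=r2, spearman_rho=rho,
                      n=len(np.asarray(y_true)))


def aggregate_over_runs(values: Sequence[float]):
    """Mean and sample standard deviation over repeated runs/splits."""
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd
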