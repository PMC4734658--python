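"""Evaluation statistics: RMSE, R-squared, F-test, Pearson and distance correlation.

The F-test follows the only construction available for a kernel predictor:
ordinary least squares of the observed values on the predictions (with
intercept), F = regression MS / residual MS on (1, n-2) degrees of freedom.
Distance correlation is the double-centered pairwise-distance statistic of
Szekely, Rizzo & Bakirov; it lies in [0, 1] and equals 1 for exact affine
dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform


@dataclass
class EvalReport:
    """Summary of a prediction run: RMSE, R^2 and the F-test."""

    rmse: float
    r_squared: float
    f_statistic: float
    f_pvalue: float
    n: int
    y: np.ndarray = field(repr=False, default=None)
    yhat: np.ndarray = field(repr=False, default=None)
    extra: dict = field(default_factory=dict, repr=False)

    def to_row(self, dataset: str = "") -> dict:
        return {
            "dataset": dataset,
            "RMSE": self.rmse,
            "R squared": self.r_squared,
            "F test": f"p={self.f_pvalue:.3g}",
            "n": self.n,
        }


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    """1 - SS_res / SS_tot; can be negative for predictors worse than the mean."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant observed values: R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def f_test(y, yhat) -> tuple[float, float]:
    """F-statistic and p-value for OLS of y on yhat (df 1, n-2).

    A perfect linear relationship gives residual MS = 0; the statistic is
    reported as inf with p = 0 in that limit.
    """
    y, yhat = _check_pair(y, yhat)
    n = y.size
    if n < 3:
        raise ValueError("F-test needs n >= 3")
    if np.ptp(yhat) == 0:
        raise ValueError("constant predictions: F-test undefined")
    slope, intercept, *_ = stats.linregress(yhat, y)
    fitted = slope * yhat + intercept
    ss_reg = float(np.sum((fitted - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    if ss_res <= 1e-300 * max(ss_reg, 1.0):
        return float("inf"), 0.0
    f = ss_reg / (ss_res / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return float(f), p


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def _double_centered_distances(v: np.ndarray) -> np.ndarray:
    if v.ndim == 1:
        v = v[:, None]
    d = squareform(pdist(v))
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation in [0, 1].

    Computed from double-centered Euclidean distance matrices; returns 0
    when either argument has zero distance variance (constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = x.shape[0]
    if nx != y.shape[0]:
        raise ValueError(f"length mismatch: {nx} vs {y.shape[0]}")
    if nx < 2:
        raise ValueError("distance correlation needs n >= 2")
    ax = _double_centered_distances(x)
    ay = _double_centered_distances(y)
    dcov2 = float((ax * ay).mean())
    dvar_x = float((ax * ax).mean())
    dvar_y = float((ay * ay).mean())
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def evaluate(y, yhat, **extra) -> EvalReport:
    """Bundle RMSE, R^2 and the F-test into an :class:`EvalReport`."""
    y, yhat = _check_pair(y, yhat)
    f, p = f_test(y, yhat)
    return EvalReport(
        rmse=rmse(y, yhat),
        r_squared=r_squared(y, yhat),
        f_statistic=f,
        f_pvalue=p,
        n=y.size,
        y=y,
        yhat=yhat,
        extra=extra,
    )
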