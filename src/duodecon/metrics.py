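"""Evaluation statistics for deconvolution: L1 error, Pearson correlation,
Lin's concordance correlation coefficient (CCC), and a linear-fitting R^2.

All moments are population moments (1/N), so ``ccc(x, x) == 1`` exactly.
Lin's CCC penalizes location and scale shifts on top of decorrelation:

    rho_c = 2 rho sigma_x sigma_y / (sigma_x^2 + sigma_y^2 + (mu_x - mu_y)^2)

The linear-fitting score is R^2 = 1 - sum (y_i - x_i)^2 / sum (x_i - xbar)^2,
so predicting the ground-truth mean everywhere scores exactly 0 and scores
can be arbitrarily negative for poor predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["l1_error", "pearson", "ccc", "r2_fit", "MetricsReport", "metrics_report"]


def _check(x, y, min_n=1):
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x, y


def l1_error(x, y) -> float:
    """Mean absolute difference between ground truth x and prediction y."""
    x, y = _check(x, y, 1)
    return float(np.mean(np.abs(y - x)))


def pearson(x, y) -> float:
    x, y = _check(x, y, 2)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc * xc))
    sy = np.sqrt(np.mean(yc * yc))
    if sx == 0 or sy == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.mean(xc * yc) / (sx * sy))


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population variances."""
    x, y = _check(x, y, 2)
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    if vx == 0 or vy == 0:
        raise ValueError("CCC undefined for a constant vector")
    cov = np.mean((x - mx) * (y - my))
    return float(2.0 * cov / (vx + vy + (mx - my) ** 2))


def r2_fit(x, y) -> float:
    """Linear-fitting score: 1 - SSE(y, x) / SS(x); constant-mean prediction -> 0."""
    x, y = _check(x, y, 2)
    ss = np.sum((x - x.mean()) ** 2)
    if ss == 0:
        raise ValueError("R^2 undefined for constant ground truth")
    return float(1.0 - np.sum((y - x) ** 2) / ss)


@dataclass
class MetricsReport:
    l1: float
    pearson: float
    ccc: float
    r2: float
    n: int
    mu_x: float
    mu_y: float
    var_x: float
    var_y: float


def metrics_report(x, y) -> MetricsReport:
    """All four statistics plus the moment components for auditing."""
    x, y = _check(x, y, 2)
    return MetricsReport(
        l1=l1_error(x, y),
        pearson=pearson(x, y),
        ccc=ccc(x, y),
        r2=r2_fit(x, y),
        n=x.size,
        mu_x=float(x.mean()),
        mu_y=float(y.mean()),
        var_x=float(np.var(x)),
        var_y=float(np.var(y)),
    )
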