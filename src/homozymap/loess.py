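"""Locally weighted scatterplot smoothing (LOESS) with tricube weights.

At each point x_i a polynomial of small degree is fitted by weighted least
squares to the ``ceil(span * n)`` nearest neighbours, with tricube weights
w = (1 - (|x - x_i| / h)^3)^3 where h is the distance to the farthest
neighbour; the smoothed value is the local polynomial evaluated at x_i.
Optional robustness iterations down-weight outliers by the bisquare of the
scaled residuals, as in classical LOWESS.

Implemented here as plain weighted least squares per point so that its
contract is directly testable against an independent normal-equations
oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LoessConfig:
    """Smoothing parameters.

    span: fraction of points in each local neighbourhood (0 < span <= 1).
    degree: local polynomial degree (1 = local linear).
    iterations: robustness (bisquare) reweighting iterations; 0 disables.
    """

    span: float = 0.3
    degree: int = 1
    iterations: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube kernel on |u| <= 1, zero outside."""
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u**3) ** 3


def loess_fit(
    x: np.ndarray, y: np.ndarray, cfg: LoessConfig | None = None
) -> np.ndarray:
    """Smoothed values at each ``x`` (strictly increasing)."""
    cfg = cfg or LoessConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    k = max(cfg.degree + 2, math.ceil(cfg.span * n))
    if n < cfg.degree + 2:
        raise ValueError(f"need at least {cfg.degree + 2} points, got {n}")
    k = min(k, n)

    robust = np.ones(n)
    fitted = np.empty(n)
    for it in range(cfg.iterations + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argpartition(d, k - 1)[:k]
            h = d[idx].max()
            w = tricube(d[idx] / h) * robust[idx]
            fitted[i] = _wls_at(x[idx] - x[i], y[idx], w, cfg.degree)
        if it < cfg.iterations:
            resid = y - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            robust = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return fitted


def _wls_at(dx: np.ndarray, y: np.ndarray, w: np.ndarray, degree: int) -> float:
    """Weighted polynomial fit in centered coordinates; value at dx = 0."""
    if w.sum() <= 0:
        # all neighbours at kernel boundary with zero weight; fall back to
        # the unweighted local mean to stay defined
        return float(y.mean())
    X = np.vander(dx, degree + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return float(coef[0])
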