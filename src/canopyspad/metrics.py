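"""Evaluation metrics for profile fits and inversion models.

Implements the four statistics used throughout the pipeline — the
coefficient of determination R², the root-mean-square error (RMSE), the
range-normalized RMSE (nRMSE), and the Pearson correlation coefficient r
with its two-sided p-value — exactly as defined:

    R²    = 1 − Σ(yᵢ − Pᵢ)² / Σ(yᵢ − ȳ)²
    RMSE  = sqrt( Σ(yᵢ − Pᵢ)² / n )
    nRMSE = RMSE / (y_max − y_min)
    r     = Σ(Xᵢ−X̄)(Yᵢ−Ȳ) / sqrt( Σ(Xᵢ−X̄)² Σ(Yᵢ−Ȳ)² )

with y the measured series, P the predicted series.  R² is not clamped:
a predictor worse than the mean yields a negative value.  Significance
screening uses the exact t-transform t = r·sqrt((n−2)/(1−r²)) with n−2
degrees of freedom at alpha = 0.05 (uncorrected; the screening is per
leaf position / per index, as in the source protocol — a Holm option is
available for users who want family-wise control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "CorrelationResult",
    "r_squared",
    "rmse",
    "nrmse",
    "pearson_r",
    "holm_adjust",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its significance screen."""

    r: float
    p_value: float | None
    n: int
    significant: bool

    def __iter__(self):  # allows r, p = pearson_r(...)
        yield self.r
        yield self.p_value


def _paired(measured, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError(
            f"measured and predicted must be 1-D and equal length, "
            f"got shapes {y.shape} and {p.shape}"
        )
    return y, p


def r_squared(measured, predicted) -> float:
    """Coefficient of determination of predicted against measured.

    Raises
    ------
    ValueError
        If the measured series is constant (zero total sum of squares)
        or has fewer than two values.
    """
    y, p = _paired(measured, predicted)
    if y.size < 2:
        raise ValueError("R² requires at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined: measured series is constant")
    ss_res = float(np.sum((y - p) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(measured, predicted) -> float:
    """Root-mean-square error, in the units of the inputs."""
    y, p = _paired(measured, predicted)
    if y.size == 0:
        raise ValueError("RMSE undefined for empty series")
    return float(np.sqrt(np.mean((y - p) ** 2)))


def nrmse(measured, predicted) -> float:
    """RMSE normalized by the range of the measured series."""
    y, _ = _paired(measured, predicted)
    rng = float(y.max() - y.min()) if y.size else 0.0
    if rng == 0.0:
        raise ValueError("nRMSE undefined: measured series has zero range")
    return rmse(measured, predicted) / rng


def pearson_r(x, y, alpha: float = ALPHA) -> CorrelationResult:
    """Pearson correlation coefficient with a two-sided t-test p-value.

    The p-value requires n >= 3; for n == 2 the coefficient alone is
    returned with ``p_value=None`` and ``significant=False``.

    Raises
    ------
    ValueError
        If either vector is constant, or n < 2.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = xv.size
    if n < 2:
        raise ValueError("correlation requires at least two pairs")
    dx = xv - xv.mean()
    dy = yv - yv.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined: constant input vector")
    r = float(np.sum(dx * dy) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))  # guard rounding overshoot
    if n < 3:
        return CorrelationResult(r=r, p_value=None, n=n, significant=False)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _sstats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p_value=p, n=n, significant=p < alpha)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values.

    Off by default everywhere in the pipeline; provided for users who
    prefer family-wise control over the raw per-test screen.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
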