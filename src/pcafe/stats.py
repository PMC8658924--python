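"""Shared statistical primitives.

Benjamini-Hochberg adjustment, the ordinary-least-squares slope test, and the
upper tail of the chi-squared distribution.  These are thin, validated wrappers
around scipy/numpy routines; each carries its own independent oracle test in
the test suite so that downstream modules can rely on their exact conventions
(strict input validation, p-values confined to (0, 1], smallest-positive-float
handling of degenerate fits).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "OlsSlopeFit",
    "bh_adjust",
    "chi2_upper_tail",
    "ols_slope_test",
    "ols_slope_test_matrix",
]

#: Smallest positive normal double; the floor for p-values of zero-residual
#: (perfect) fits and for underflowed tail probabilities, keeping p in (0, 1].
TINY_P = float(np.finfo(np.float64).tiny)


def _validate_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-value vector must be one-dimensional and nonempty")
    if not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        bad = p[(p <= 0.0) | (p > 1.0)]
        raise ValueError(f"p-values must lie in (0, 1]; offending values: {bad[:5]}")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    p : array-like of float
        Raw p-values, each in (0, 1].

    Returns
    -------
    numpy.ndarray
        Adjusted p-values in the input's order: for the k-th order statistic,
        ``min_{j >= k} (n * p_(j) / j)`` capped at 1.  Tied inputs share the
        adjusted value, and the output is elementwise >= the input.
    """
    p = _validate_pvalues(p)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adjusted_sorted, None, 1.0, out=adjusted_sorted)
    adjusted = np.empty_like(adjusted_sorted)
    adjusted[order] = adjusted_sorted
    return adjusted


class OlsSlopeFit(NamedTuple):
    """Simple-regression fit of ``y = intercept + slope * t``."""

    intercept: float
    slope: float
    p_value: float


def ols_slope_test(y, t) -> OlsSlopeFit:
    """Ordinary least squares of ``y`` on ``t`` with a two-sided slope t-test.

    Requires at least 3 observations and a non-constant ``t``.  A zero-residual
    (perfect) fit returns the smallest positive normal float as its p-value so
    that downstream logs and BH adjustment stay finite.
    """
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("y and t must be one-dimensional arrays of equal length")
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
        raise ValueError("y and t must be finite")
    intercept, slope, p = _slope_test_core(y[np.newaxis, :], t)
    return OlsSlopeFit(float(intercept[0]), float(slope[0]), float(p[0]))


def ols_slope_test_matrix(Y, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise OLS slope test: each row of ``Y`` is regressed on ``t``.

    Returns ``(intercept, slope, p_value)`` arrays of length ``Y.shape[0]``.
    Vectorized equivalent of :func:`ols_slope_test`; used by the per-probe
    regression baseline where tens of thousands of fits are needed.
    """
    Y = np.asarray(Y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if Y.ndim != 2 or t.ndim != 1 or Y.shape[1] != t.size:
        raise ValueError("Y must be (rows x n) and t of length n")
    if t.size < 3:
        raise ValueError(f"need at least 3 observations, got {t.size}")
    if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(t))):
        raise ValueError("Y and t must be finite")
    return _slope_test_core(Y, t)


def _slope_test_core(Y: np.ndarray, t: np.ndarray):
    n = t.size
    t_center = t - t.mean()
    sxx = float(t_center @ t_center)
    if sxx == 0.0:
        raise ValueError("t is constant; the slope is not identifiable")
    y_mean = Y.mean(axis=1)
    sxy = Y @ t_center
    slope = sxy / sxx
    intercept = y_mean - slope * t.mean()
    residuals = Y - intercept[:, None] - slope[:, None] * t[None, :]
    rss = np.einsum("ij,ij->i", residuals, residuals)
    # Guard against tiny negative rounding and against perfect fits: a perfect
    # fit has no residual variance, so the t statistic diverges; map it to the
    # smallest positive p rather than dividing by zero.
    total_ss = np.einsum("ij,ij->i", Y - y_mean[:, None], Y - y_mean[:, None])
    # A (numerically) constant y is a zero-slope fit with p = 1, not a perfect
    # fit: without this guard, rounding noise of order eps*|y| yields a tiny
    # slope AND a tiny residual whose ratio is an O(1) t statistic.
    constant = total_ss <= t.size * (1e-12 * np.maximum(np.abs(y_mean), 1e-300)) ** 2
    perfect = (rss <= 1e-12 * np.maximum(total_ss, 1.0)) & ~constant
    safe_rss = np.where(perfect | constant, 1.0, rss)
    se = np.sqrt(safe_rss / ((n - 2) * sxx))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0.0, slope / se, 0.0)
    tstat[constant] = 0.0
    p = 2.0 * _scipy_stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, TINY_P, 1.0)
    p[perfect] = TINY_P
    p[constant] = 1.0
    return intercept, slope, p


def chi2_upper_tail(x, df: int):
    """Upper-tail probability ``P[chi2_df > x]``, confined to (0, 1].

    Accepts a scalar or an array of nonnegative values; ``df`` must be a
    positive integer.  Underflowed tails are floored at the smallest positive
    normal float.
    """
    if int(df) != df or df < 1:
        raise ValueError(f"df must be a positive integer, got {df!r}")
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0.0) or not np.all(np.isfinite(arr)):
        raise ValueError("chi-squared statistic must be finite and nonnegative")
    p = _scipy_stats.chi2.sf(arr, df=int(df))
    p = np.clip(p, TINY_P, 1.0)
    if np.isscalar(x) or arr.ndim == 0:
        return float(p)
    return p
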