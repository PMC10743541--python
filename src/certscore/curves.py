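"""Winsorized loess risk curves.

Plots of hypertension risk against a lipid predictor: the predictor is
winsorized at its 1st/99th percentiles to suppress long uninformative tails,
then the binary outcome is smoothed by locally weighted polynomial regression
(loess: tricube weights, local quadratic fit, span 0.75 by default) on an
evenly spaced grid, with a pointwise normal-approximation 95% band.

The winsorization cut-points are nearest order statistics (the largest data
value at or below the lower percentile rank, the smallest at or above the
upper rank), which makes the operation exactly idempotent: clipping never
moves the cut-defining order statistics, so a second pass is a no-op.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InsufficientDataError

__all__ = ["RiskCurve", "winsorize", "fit_risk_curve", "risk_curve"]


@dataclass(frozen=True)
class RiskCurve:
    """Loess-smoothed risk curve on a fixed predictor grid."""

    predictor_name: str
    grid: np.ndarray
    fitted_risk: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    span: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise DataError(f"{self.predictor_name}: grid must be strictly increasing")
        if not (
            np.all(self.band_low <= self.fitted_risk + 1e-12)
            and np.all(self.fitted_risk <= self.band_high + 1e-12)
        ):
            raise DataError("confidence band does not bracket the fitted curve")
        if not np.all(np.isfinite(self.fitted_risk)):
            raise DataError("non-finite fitted values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                "fitted_risk": self.fitted_risk,
                "band_low": self.band_low,
                "band_high": self.band_high,
            }
        )


def winsorize(values, lower_pct: float = 1.0, upper_pct: float = 99.0) -> np.ndarray:
    """Clip values at the ``lower_pct``/``upper_pct`` percentile cut-points.

    Cut-points are nearest order statistics (floor/ceil of the percentile
    rank), so the transform is idempotent; interior values are untouched.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ConfigurationError(
            f"invalid winsorization percentiles ({lower_pct}, {upper_pct})"
        )
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("winsorize needs at least 2 values")
    srt = np.sort(arr)
    n = arr.size
    lo = srt[math.floor(lower_pct / 100.0 * (n - 1))]
    hi = srt[math.ceil(upper_pct / 100.0 * (n - 1))]
    return np.clip(arr, lo, hi)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def fit_risk_curve(
    x,
    y,
    span: float = 0.75,
    predictor_name: str = "x",
    degree: int = 2,
    n_grid: int = 100,
    conf: float = 0.95,
) -> RiskCurve:
    """Loess fit of a binary outcome on a (winsorized) predictor.

    At each of ``n_grid`` evenly spaced grid points inside the data range, a
    weighted polynomial of the given degree is fitted with tricube weights
    over the nearest ``span`` fraction of observations; the fitted value is
    its intercept.  The band is the pointwise normal interval
    ``fit +- z * s * ||l||`` where ``l`` is the equivalent smoothing kernel
    and ``s^2`` the residual variance of the smooth.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-d arrays of equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("y must be binary (0/1)")
    if not (0 < span <= 1):
        raise ConfigurationError(f"span must be in (0, 1], got {span}")
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 2)
    if n < degree + 3 or k > n:
        raise InsufficientDataError(
            f"need at least {degree + 3} points for a degree-{degree} loess "
            f"window, got {n}"
        )
    if np.ptp(x) == 0:
        raise DataError("predictor is constant; no curve to fit")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    grid = np.linspace(xs[0], xs[-1], n_grid)

    fitted = np.empty(n_grid)
    l_norm2 = np.empty(n_grid)
    powers = np.arange(degree + 1)
    for i, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:  # heavy ties at x0: fall back to the tied neighbourhood
            w = (d == 0).astype(float)
        else:
            w = _tricube(d / h)
        use = w > 0
        X = (xs[use, None] - x0) ** powers[None, :]
        wx = w[use]
        A = X.T @ (wx[:, None] * X)
        B = X.T * wx  # (p+1, m): maps y -> coefficients
        coef_map = np.linalg.pinv(A) @ B
        l_local = coef_map[0]
        fitted[i] = l_local @ ys[use]
        l_norm2[i] = float(l_local @ l_local)

    # residual variance of the smooth, via interpolation onto the data
    resid = ys - np.interp(xs, grid, fitted)
    dof = max(n - (degree + 1), 1)
    s2 = float(resid @ resid) / dof
    z = float(_norm_ppf(0.5 + conf / 2.0))
    half = z * np.sqrt(s2 * l_norm2)
    return RiskCurve(
        predictor_name=predictor_name,
        grid=grid,
        fitted_risk=fitted,
        band_low=fitted - half,
        band_high=fitted + half,
        span=span,
    )


def _norm_ppf(q: float) -> float:
    from scipy import stats

    return stats.norm.ppf(q)


def risk_curve(
    cohort: pd.DataFrame,
    predictor: str,
    outcome: str = "prevalent",
    span: float = 0.75,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    **kwargs,
) -> RiskCurve:
    """Convenience wrapper: winsorize a cohort predictor column and fit the
    risk curve against prevalent or new-onset hypertension."""
    if outcome == "prevalent":
        y = cohort["prevalent_htn"].astype(float).to_numpy()
        df = cohort
    elif outcome == "new_onset":
        df = cohort.loc[~cohort["prevalent_htn"].astype(bool)]
        y = df["event_new_onset"].astype(float).to_numpy()
    else:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    xw = winsorize(df[predictor].astype(float).to_numpy(), lower_pct, upper_pct)
    return fit_risk_curve(xw, y, span=span, predictor_name=predictor, **kwargs)
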