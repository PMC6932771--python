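"""Sigmoidal edge regression with residual bootstrapping.

Each edge of a cascade relates the activity of a parent node (``x``) to the
activity of its child node (``y``) through a Hill-type sigmoid:

    increasing:  y = ymax * (x/K)^h / (1 + (x/K)^h)
    decreasing:  y = ymax / (1 + (x/K)^h)

``ymax`` is the saturating activity of the child (child units), ``K`` the
half-maximal parent activity (parent units), and ``h`` a dimensionless
steepness exponent.  The direction is selected from the sign of Kendall's
tau-b on the raw data.  Coefficient uncertainty is quantified by a residual
bootstrap: residuals are resampled with replacement onto the fitted curve,
each pseudo-dataset is refit, and the pooled (original + bootstrap)
coefficient values yield order-statistic 95% confidence intervals.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("cascademc")

__all__ = [
    "SigmoidDirection",
    "SigmoidCoefficients",
    "DoseResponseData",
    "EdgeFit",
    "BootstrapCI",
    "CoefficientInterval",
    "FitError",
    "BootstrapDegenerateError",
    "kendall_tau",
    "select_direction",
    "sigmoid_eval",
    "fit_edge",
    "bootstrap_edge",
]

#: two-sided 95% normal quantile used throughout for CI <-> sd conversion
Z_95 = 1.959964

#: fraction of bootstrap refits that may fail before the CI is declared
#: unreliable
MAX_BOOTSTRAP_FAILURE_FRACTION = 0.20


class FitError(RuntimeError):
    """Nonlinear least-squares fit failed after all restarts."""


class BootstrapDegenerateError(RuntimeError):
    """Too many bootstrap refits failed for the CI to be trustworthy."""


class SigmoidDirection(enum.Enum):
    """Trend of the child response as the parent activity grows."""

    INCREASING = "increasing"
    DECREASING = "decreasing"


@dataclass(frozen=True)
class SigmoidCoefficients:
    """Coefficients (ymax, K, h) of a Hill-type sigmoid; all positive."""

    ymax: float
    K: float
    h: float

    def __post_init__(self) -> None:
        for name in ("ymax", "K", "h"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"coefficient {name} must be finite and > 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ymax, self.K, self.h], dtype=float)


@dataclass(frozen=True)
class DoseResponseData:
    """Paired parent/child activities for one edge.

    ``x`` holds the parent-node activities (nonnegative; e.g. fold change or
    a concentration), ``y`` the child-node activities measured under the same
    conditions.  At least 4 points are required so the 3-coefficient sigmoid
    retains a residual degree of freedom.
    """

    x: np.ndarray
    y: np.ndarray

    def __init__(self, x: Sequence[float], y: Sequence[float]):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if len(x) != len(y):
            raise ValueError(f"length mismatch: {len(x)} x values vs {len(y)} y values")
        if len(x) < 4:
            raise ValueError(f"need at least 4 data points to fit 3 coefficients, got {len(x)}")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise ValueError("all x and y values must be finite")
        if np.any(x < 0):
            raise ValueError("parent activities x must be nonnegative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b rank correlation between two equal-length sequences.

    The tie-adjusted variant is used because dose-response tables routinely
    repeat x levels.  Returns a value in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations for a rank correlation")
    tau = stats.kendalltau(x, y).statistic
    if math.isnan(tau):  # all-tied degenerate input: no trend
        return 0.0
    return float(tau)


def select_direction(data: DoseResponseData) -> SigmoidDirection:
    """Pick the sigmoid family from the sign of Kendall's tau.

    tau > 0 (positive trend) selects the increasing form; tau <= 0 (negative
    or unchanging trend) selects the decreasing form.
    """
    tau = kendall_tau(data.x, data.y)
    return SigmoidDirection.INCREASING if tau > 0 else SigmoidDirection.DECREASING


def _sigmoid_array(
    x: np.ndarray, ymax: float, K: float, h: float, direction: SigmoidDirection
) -> np.ndarray:
    # (x/K)^h with the x=0 limit handled explicitly: 0^h -> 0 for all h > 0
    with np.errstate(divide="ignore", over="ignore"):
        r = np.where(x > 0, np.power(x / K, h), 0.0)
    if direction is SigmoidDirection.INCREASING:
        with np.errstate(invalid="ignore"):
            out = np.where(np.isinf(r), ymax, ymax * r / (1.0 + r))
    else:
        out = ymax / (1.0 + r)
    return out


def sigmoid_eval(
    x: float | Sequence[float],
    coefficients: SigmoidCoefficients,
    direction: SigmoidDirection,
) -> float | np.ndarray:
    """Evaluate the Hill sigmoid at parent activity ``x`` (scalar or array).

    The result always lies in [0, ymax]; x must be nonnegative.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("parent activity x must be nonnegative")
    out = _sigmoid_array(
        np.atleast_1d(arr), coefficients.ymax, coefficients.K, coefficients.h, direction
    )
    if arr.ndim == 0:
        return float(out[0])
    return out


@dataclass(frozen=True)
class EdgeFit:
    """Least-squares sigmoid fit for one edge, with its residual vector."""

    direction: SigmoidDirection
    coefficients: SigmoidCoefficients
    residuals: np.ndarray
    data: DoseResponseData

    @property
    def fitted_values(self) -> np.ndarray:
        return sigmoid_eval(self.data.x, self.coefficients, self.direction)

    @property
    def ssr(self) -> float:
        return float(np.sum(self.residuals**2))


def _initial_K(x: np.ndarray, y: np.ndarray, ymax0: float, direction: SigmoidDirection) -> float:
    """x at which the data first crosses half of ymax0, by linear interpolation."""
    half = 0.5 * ymax0
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # for a decreasing trend the crossing is downward; scan in x order either way
    for i in range(len(xs) - 1):
        y0, y1 = ys[i], ys[i + 1]
        if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
            t = (half - y0) / (y1 - y0)
            k = xs[i] + t * (xs[i + 1] - xs[i])
            if k > 0:
                return float(k)
    med = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    return med if med > 0 else 1.0


_H_RESTARTS = (1.0, 0.5, 2.0, 4.0)


def _fit_least_squares(
    x: np.ndarray, y: np.ndarray, direction: SigmoidDirection, p0: np.ndarray
) -> tuple[np.ndarray, float] | None:
    """One bounded least-squares attempt; returns (coefs, ssr) or None."""

    def resid(c: np.ndarray) -> np.ndarray:
        return _sigmoid_array(x, c[0], c[1], c[2], direction) - y

    increasing = direction is SigmoidDirection.INCREASING

    def jac(c: np.ndarray) -> np.ndarray:
        ymax, K, h = c
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            u = np.where(x > 0, np.power(x / K, h), 0.0)
            logxk = np.where(x > 0, np.log(x / K), 0.0)
            denom = (1.0 + u) ** 2
            if increasing:
                d_ymax = u / (1.0 + u)
                d_u = ymax / denom
            else:
                d_ymax = 1.0 / (1.0 + u)
                d_u = -ymax / denom
            d_K = d_u * (-h * u / K)
            d_h = d_u * (u * logxk)
        # saturated points (u -> inf): f -> ymax (increasing) or 0 (decreasing),
        # insensitive to K and h
        sat = ~np.isfinite(u)
        if np.any(sat):
            d_ymax = np.where(sat, 1.0 if increasing else 0.0, d_ymax)
            d_K = np.where(sat, 0.0, d_K)
            d_h = np.where(sat, 0.0, d_h)
        return np.column_stack([d_ymax, d_K, d_h])

    tiny = 1e-12
    try:
        sol = optimize.least_squares(
            resid,
            np.clip(p0, tiny, None),
            jac=jac,
            bounds=([tiny, tiny, tiny], [np.inf, np.inf, np.inf]),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=5000,
        )
    except Exception:
        return None
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return None
    return sol.x, float(2 * sol.cost)


def fit_edge(
    data: DoseResponseData,
    direction: SigmoidDirection | None = None,
) -> EdgeFit:
    """Fit the Hill sigmoid to one edge's paired data by least squares.

    All three coefficients are constrained positive.  Starting values follow
    standard Hill-fit practice: ymax0 = max|y|, K0 = the half-maximum
    crossing of the data (median x as fallback), h0 = 1 with restarts at
    h0 in {0.5, 2, 4}.  The best converged restart (lowest SSR) wins.

    Raises
    ------
    FitError
        If no restart converges.
    """
    if direction is None:
        direction = select_direction(data)
    x, y = data.x, data.y

    ymax0 = float(np.max(np.abs(y)))
    if ymax0 <= 0:
        ymax0 = 1.0
    K0 = _initial_K(x, y, ymax0, direction)

    best: tuple[np.ndarray, float] | None = None
    for h0 in _H_RESTARTS:
        res = _fit_least_squares(x, y, direction, np.array([ymax0, K0, h0]))
        if res is not None and (best is None or res[1] < best[1]):
            best = res
            if best[1] < 1e-24:  # exact fit, no point restarting
                break
    if best is None:
        raise FitError(
            f"sigmoid fit failed to converge for any start h0 in {_H_RESTARTS} "
            f"(n={len(data)}, direction={direction.value})"
        )
    coefs = SigmoidCoefficients(*best[0])
    residuals = y - _sigmoid_array(x, coefs.ymax, coefs.K, coefs.h, direction)
    return EdgeFit(direction=direction, coefficients=coefs, residuals=residuals, data=data)


@dataclass(frozen=True)
class CoefficientInterval:
    """Order-statistic 95% interval and point estimate for one coefficient."""

    lower: float
    upper: float
    point: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class BootstrapCI:
    """Residual-bootstrap confidence intervals for an edge's coefficients.

    ``intervals`` maps coefficient name (ymax, K, h) to its interval.
    ``samples`` holds the pooled coefficient vectors, original fit first,
    one row per converged resample after it — kept so the ensemble module's
    bootstrap-curve mode can draw whole fitted curves.
    """

    intervals: dict[str, CoefficientInterval]
    m: int
    n_failed: int
    samples: np.ndarray = field(repr=False)
    seed: int | None = None

    def __getitem__(self, name: str) -> CoefficientInterval:
        return self.intervals[name]


def _ci_ranks(m: int) -> tuple[int, int]:
    """1-based pooled-sample ranks of the 95% CI bounds for m resamples.

    (m+1)*0.025 is exact for m = 999 (rank 25); otherwise the lower rank is
    floored (>= 1) and the upper rank is ceiled, which can only widen the
    interval.
    """
    lo = max(1, math.floor((m + 1) * 0.025))
    hi = min(m + 1, math.ceil((m + 1) * 0.975))
    return lo, hi


def bootstrap_edge(fit: EdgeFit, m: int = 999, rng_seed: int | None = None) -> BootstrapCI:
    """Residual-bootstrap 95% CIs for an edge's sigmoid coefficients.

    For each of ``m`` resamples the residuals are drawn uniformly with
    replacement, added to the fitted values, and the sigmoid is refit with
    the direction held fixed.  The m bootstrap coefficient vectors are pooled
    with the original fit, each coefficient column is sorted ascending, and
    the (m+1)*0.025-th and (m+1)*0.975-th order statistics (1-based) are the
    CI bounds.

    Individual refit failures are skipped and counted; if more than 20% of
    the resamples fail, :class:`BootstrapDegenerateError` is raised.
    """
    if m < 39:
        raise ValueError(f"m must be >= 39 so that (m+1)*0.025 >= 1, got {m}")
    rng = np.random.default_rng(rng_seed)
    x = fit.data.x
    yhat = fit.fitted_values
    residuals = fit.residuals
    n = len(residuals)
    point = fit.coefficients.as_array()

    rows = [point]
    n_failed = 0
    p0 = point.copy()
    for _ in range(m):
        idx = rng.integers(0, n, size=n)
        y_star = yhat + residuals[idx]
        # warm-start at the original coefficients; fall back to the standard
        # restart ladder on failure
        res = _fit_least_squares(x, y_star, fit.direction, p0)
        if res is None:
            try:
                refit = fit_edge(DoseResponseData(x, y_star), fit.direction)
                res = (refit.coefficients.as_array(), refit.ssr)
            except (FitError, ValueError):
                res = None
        if res is None:
            n_failed += 1
        else:
            rows.append(res[0])

    if n_failed > MAX_BOOTSTRAP_FAILURE_FRACTION * m:
        raise BootstrapDegenerateError(
            f"{n_failed}/{m} bootstrap refits failed (> {MAX_BOOTSTRAP_FAILURE_FRACTION:.0%})"
        )
    if n_failed:
        logger.info("bootstrap: %d/%d resample refits failed and were skipped", n_failed, m)

    samples = np.asarray(rows)
    # ranks are defined on the achieved pool (original + converged resamples);
    # with zero failures this is exactly the (m+1)-value pool
    lo_rank, hi_rank = _ci_ranks(samples.shape[0] - 1)
    lo_idx = lo_rank - 1
    hi_idx = hi_rank - 1
    intervals = {}
    for j, name in enumerate(("ymax", "K", "h")):
        col = np.sort(samples[:, j])
        intervals[name] = CoefficientInterval(
            lower=float(col[lo_idx]), upper=float(col[hi_idx]), point=float(point[j])
        )
    return BootstrapCI(intervals=intervals, m=m, n_failed=n_failed, samples=samples, seed=rng_seed)
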