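"""Two-breakpoint piecewise linear regression through the conditional mean.

The model ``y = b0 + b1*x + b2*(x - a1)_+ + b3*(x - a2)_+ + e`` is fitted
by nonlinear least squares.  Because the model is linear in the betas for
fixed breakpoints, the sum of squared errors is profiled over the knot
pair: an exhaustive grid over admissible ``(a1, a2)`` locates the basin,
and a derivative-free local search refines it.  This sidesteps the hinge
non-smoothness that trips generic gradient-based NLS.

Inference (breakpoint confidence intervals, segment-slope t tests, and
the t-based prediction band) uses standard NLS asymptotics: the Jacobian
of the mean function in all six parameters at the optimum, with
``V = sigma^2 (J'J)^{-1}`` on ``n - 6`` residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._knots import (ConvergenceError, DegenerateFitError, admissible,
                     knot_grid)
from .core import (BreakpointParams, InvalidInputError, SegmentSlopes,
                   XYData, hinge_basis, piecewise_mean)

__all__ = ["PlrmFit", "IntervalEstimate", "fit_plrm", "plrm_breakpoint_ci",
           "plrm_prediction_band", "slope_tests"]

#: linear map from theta = (b0, b1, b2, b3, a1, a2) to the three slopes
_SLOPE_L = np.array([
    [0, 1, 0, 0, 0, 0],
    [0, 1, 1, 0, 0, 0],
    [0, 1, 1, 1, 0, 0],
], dtype=float)


@dataclass
class IntervalEstimate:
    """A point estimate with a (lower, upper) interval at level ``level``."""

    estimate: float
    lower: float
    upper: float
    level: float
    estimate_outside: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise InvalidInputError("interval limits out of order")
        # percentile intervals can, pathologically, exclude the estimate;
        # flag rather than silently reorder
        self.estimate_outside = not (
            self.lower <= self.estimate <= self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class PlrmFit:
    """Result of a least-squares two-breakpoint fit."""

    data: XYData
    params: BreakpointParams
    cov: np.ndarray          # 6x6 covariance of (b0..b3, a1, a2)
    fitted: np.ndarray
    residuals: np.ndarray
    sse: float
    slopes: SegmentSlopes

    @property
    def df_resid(self) -> int:
        return self.data.n - 6

    @property
    def sigma(self) -> float:
        return self.params.sigma

    def predict(self, x) -> np.ndarray | float:
        return piecewise_mean(x, self.params)


def _profiled_sse(data: XYData, a1: float, a2: float,
                  ) -> tuple[float, np.ndarray]:
    """Least-squares over betas for fixed knots; (sse, beta)."""
    X = hinge_basis(data.x, a1, a2)
    beta, _, _, _ = np.linalg.lstsq(X, data.y, rcond=None)
    r = data.y - X @ beta
    return float(r @ r), beta


def _mean_jacobian(x: np.ndarray, params: BreakpointParams) -> np.ndarray:
    """Analytic Jacobian of the mean in (b0..b3, a1, a2), shape (n, 6).

    The alpha derivatives are ``-b2 * 1{x > a1}`` and ``-b3 * 1{x > a2}``
    (defined almost everywhere; the hinge kinks have measure zero).
    """
    J = np.empty((x.shape[0], 6))
    J[:, :4] = hinge_basis(x, params.alpha1, params.alpha2)
    J[:, 4] = -params.beta2 * (x > params.alpha1)
    J[:, 5] = -params.beta3 * (x > params.alpha2)
    return J


def fit_plrm(data: XYData, init: BreakpointParams | None = None,
             *, grid_size: int = 41, warm: bool = False) -> PlrmFit:
    """Fit the two-breakpoint mean model by profiled least squares.

    Parameters
    ----------
    data : XYData
        Observations; at least 8 points.
    init : BreakpointParams, optional
        Starting values (typically from loess screening).  With
        ``warm=False`` they only seed an extra refinement start, since
        the knot grid is searched exhaustively anyway.
    grid_size : int
        Number of candidate knot locations per axis.
    warm : bool
        If true, skip the global grid and refine locally from ``init``
        (used for bootstrap refits, where the solution is known to be
        near ``init``).
    """
    x, y = data.x, data.y
    grid, min_gap = knot_grid(data, grid_size)

    def sse_of(a: np.ndarray) -> float:
        # large finite penalty (not inf) keeps the simplex arithmetic clean
        if not admissible(x, a[0], a[1], min_gap):
            return 1e30
        return _profiled_sse(data, a[0], a[1])[0]

    starts: list[np.ndarray] = []
    if warm:
        if init is None:
            raise InvalidInputError("warm refit requires init")
        starts.append(init.alpha)
    else:
        best: tuple[float, np.ndarray] | None = None
        for i, a1 in enumerate(grid):
            for a2 in grid[i + 1:]:
                s = sse_of(np.array([a1, a2]))
                if s < 1e29 and (best is None or s < best[0]):
                    best = (s, np.array([a1, a2]))
        if best is None:
            raise DegenerateFitError(
                "no admissible breakpoint pair on the search grid")
        starts.append(best[1])
        if init is not None and admissible(x, init.alpha1, init.alpha2,
                                           min_gap):
            starts.append(init.alpha)
        # multistart guard: perturb the grid winner by 5% of the x range
        delta = 0.05 * np.ptp(x)
        starts.append(best[1] + np.array([delta, -delta]))

    best_alpha, best_sse = None, np.inf
    for a0 in starts:
        res = optimize.minimize(
            sse_of, a0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400})
        if res.fun < min(best_sse, 1e29):
            best_sse, best_alpha = res.fun, res.x
    if best_alpha is None:
        raise ConvergenceError("no refinement start converged")

    a1, a2 = float(best_alpha[0]), float(best_alpha[1])
    if a2 - a1 < min_gap:
        raise DegenerateFitError(
            f"breakpoints collapsed: alpha2 - alpha1 = {a2 - a1:.4g}")
    sse, beta = _profiled_sse(data, a1, a2)
    n = data.n
    sigma2 = sse / (n - 6)
    params = BreakpointParams(*beta, a1, a2, sigma=float(np.sqrt(sigma2)))

    J = _mean_jacobian(x, params)
    JtJ = J.T @ J
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(JtJ)
    fitted = piecewise_mean(x, params)
    slopes = _slope_inference(params, cov, n - 6)
    return PlrmFit(data=data, params=params, cov=cov, fitted=fitted,
                   residuals=y - fitted, sse=sse, slopes=slopes)


def _slope_inference(params: BreakpointParams, cov: np.ndarray,
                     df: int) -> SegmentSlopes:
    s = _SLOPE_L @ params.theta
    var = np.einsum("ij,jk,ik->i", _SLOPE_L, cov, _SLOPE_L)
    se = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, s / se, np.inf * np.sign(s))
    p = 2 * stats.t.sf(np.abs(t), df)
    return SegmentSlopes(slopes=s, se=se, t=t, p=p)


def slope_tests(fit: PlrmFit) -> SegmentSlopes:
    """Two-sided t tests for the three segment slopes on n - 6 df."""
    return fit.slopes


def plrm_breakpoint_ci(fit: PlrmFit, level: float = 0.95,
                       ) -> tuple[IntervalEstimate, IntervalEstimate]:
    """Delta-method t confidence intervals for the two breakpoints."""
    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0, 1)")
    var_a = np.diag(fit.cov)[4:6]
    if np.any(~np.isfinite(var_a)) or np.any(var_a < 0):
        raise InvalidInputError(
            "singular covariance: data are uninformative about a breakpoint")
    se = np.sqrt(var_a)
    tq = stats.t.ppf(1 - (1 - level) / 2, fit.df_resid)
    out = []
    for ahat, s in zip(fit.params.alpha, se):
        out.append(IntervalEstimate(float(ahat), float(ahat - tq * s),
                                    float(ahat + tq * s), level))
    return out[0], out[1]


def plrm_prediction_band(fit: PlrmFit, level: float = 0.95,
                         grid: np.ndarray | None = None,
                         *, allow_extrapolation: bool = False):
    """Parametric t prediction band for a new response at each grid x.

    Half-width at x is ``t_{1-(1-level)/2, n-6} * sqrt(sigma^2 + g'Vg)``
    where ``g`` is the parameter gradient of the mean at x.
    """
    from .bootstrap import PredictionBand  # shared band container

    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0, 1)")
    if grid is None:
        grid = np.sort(fit.data.x)
    grid = np.asarray(grid, dtype=float)
    lo, hi = np.min(fit.data.x), np.max(fit.data.x)
    if not allow_extrapolation and (np.min(grid) < lo or np.max(grid) > hi):
        raise InvalidInputError(
            "grid extends beyond the observed x range; pass "
            "allow_extrapolation=True to override")
    yhat = piecewise_mean(grid, fit.params)
    G = _mean_jacobian(grid, fit.params)
    var_mean = np.einsum("ij,jk,ik->i", G, fit.cov, G)
    sigma2 = fit.sigma ** 2
    tq = stats.t.ppf(1 - (1 - level) / 2, fit.df_resid)
    half = tq * np.sqrt(np.clip(sigma2 + var_mean, 0.0, None))
    return PredictionBand(x=grid, lower=yhat - half, upper=yhat + half,
                          level=level)
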