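"""Bootstrap inference: prediction bands and breakpoint intervals.

Two resampling procedures:

* a model-agnostic residual bootstrap that turns any refittable smoother
  or regression into a pointwise prediction band for a new response
  (works with loess, the quantile fit, and — optionally — the
  least-squares fit, whose band is normally parametric);
* a wild bootstrap for the breakpoints of the quantile fit, which
  multiplies normalised absolute residuals by asymmetric two-point
  weights so the resampled errors retain the tau-quantile structure.

Both are fully reproducible: one master seed spawns independent
per-replicate substreams, so a skipped replicate cannot shift the draws
of later ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .core import BreakpointParams, InvalidInputError, XYData
from .plrm import IntervalEstimate
from .pqrm import QuantileFit, fit_pqrm

__all__ = [
    "PredictionBand", "WildScheme", "BootstrapDiagnostics",
    "bootstrap_prediction_band", "wild_bootstrap_breakpoint_ci",
    "psi", "density_at_zero",
    "LoessModel", "PqrmModel", "PlrmModel",
]


class DensityEstimationError(RuntimeError):
    pass


class TooManyFailuresError(RuntimeError):
    pass


@dataclass
class PredictionBand:
    """Pointwise lower/upper limits for a new response at each grid x."""

    x: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (self.x.shape == self.lower.shape == self.upper.shape):
            raise InvalidInputError("band arrays must share one shape")
        if np.any(self.lower > self.upper + 1e-12):
            raise InvalidInputError("band has lower > upper")

    @property
    def area(self) -> float:
        """Trapezoidal integral of (upper - lower) over the grid."""
        if self.x.size < 2:
            return 0.0
        if np.any(np.diff(self.x) < 0):
            raise InvalidInputError("band grid must be sorted ascending")
        return float(integrate.trapezoid(self.upper - self.lower, self.x))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.x, "lower": self.lower,
                             "upper": self.upper, "level": self.level})


@dataclass
class BootstrapDiagnostics:
    requested: int
    successful: int
    seed: int | None
    failures: list[str] = field(default_factory=list)


def psi(u, tau: float) -> np.ndarray | float:
    """Quantile score ``tau - 1{u < 0}``; by convention ``psi(0) = tau``."""
    u = np.asarray(u, dtype=float)
    out = tau - (u < 0)
    return float(out) if out.ndim == 0 else out


def density_at_zero(residuals: np.ndarray) -> float:
    """Gaussian-kernel density estimate of the residuals at zero.

    Bandwidth by Silverman's rule, ``0.9 min(sd, IQR/1.34) n^{-1/5}``.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 8:
        raise InvalidInputError("need at least 8 residuals")
    sd = float(np.std(r, ddof=1))
    iqr = float(np.subtract(*np.percentile(r, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * r.size ** (-1 / 5)
    if not np.isfinite(bw) or bw <= 0:
        raise DensityEstimationError(
            "zero bandwidth: residuals have no spread")
    z = r / bw
    f0 = float(np.mean(np.exp(-0.5 * z * z)) / (bw * np.sqrt(2 * np.pi)))
    if not np.isfinite(f0) or f0 <= 0:
        raise DensityEstimationError("nonpositive density estimate at 0")
    return f0


@dataclass
class WildScheme:
    """Ingredients of the wild bootstrap for quantile residuals.

    Leverage weights ``h_i = x_i^2 / sum_j x_j^2`` (taken literally on
    the raw predictor), the residual density at zero, and the two-point
    weight law ``w = 2(1 - tau)`` w.p. ``1 - tau``, ``-2 tau`` w.p.
    ``tau`` — at the median the weights are simply +/-1.
    """

    tau: float
    leverage: np.ndarray
    f0: float

    @classmethod
    def from_fit(cls, fit: QuantileFit) -> "WildScheme":
        x = fit.data.x
        lev = x ** 2 / np.sum(x ** 2)
        return cls(tau=fit.tau, leverage=lev,
                   f0=density_at_zero(fit.residuals))

    def normalize(self, residuals: np.ndarray) -> np.ndarray:
        """Centre residuals by the first-order quantile bias term:
        ``e_i - h_i psi_tau(e_i) / f(0)``."""
        return residuals - self.leverage * psi(residuals, self.tau) / self.f0

    def draw_weights(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.where(rng.random(size) < self.tau,
                        -2 * self.tau, 2 * (1 - self.tau))


def _substreams(seed, count: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(count)]


def bootstrap_prediction_band(model, data: XYData, level: float = 0.95,
                              B: int = 1000, seed: int | None = None,
                              *, min_success_frac: float = 0.9,
                              ) -> tuple[PredictionBand,
                                         BootstrapDiagnostics]:
    """Residual-bootstrap prediction band around any refittable model.

    ``model.fit(data)`` must return a callable predictor of the response
    at arbitrary x.  Per replicate: centred residuals are resampled onto
    the fitted curve, the model is refitted, its own centred residuals
    are resampled once more, and the "predicted residual"
    ``m_hat(x_i) - m_hat*(x_i) + e**_i`` is recorded; band limits are
    the pointwise empirical ``(1 -/+ level)/2`` quantiles of these
    added back to the fitted curve.

    ``level`` may be a scalar or a sequence of levels (bands at several
    levels share the same replicate draws and are therefore nested).
    """
    levels = np.atleast_1d(np.asarray(level, dtype=float))
    if np.any((levels <= 0) | (levels >= 1)):
        raise InvalidInputError("level must lie in (0, 1)")
    if B < 100:
        raise InvalidInputError("B must be at least 100")

    predictor = model.fit(data)
    yhat = np.asarray(predictor(data.x), dtype=float)
    resid = data.y - yhat
    resid_c = resid - resid.mean()

    n = data.n
    pred_resid = np.empty((B, n))
    ok = np.zeros(B, dtype=bool)
    failures: list[str] = []
    for b, rng in enumerate(_substreams(seed, B)):
        eps_star = rng.choice(resid_c, size=n, replace=True)
        y_star = yhat + eps_star
        try:
            pred_b = model.fit(XYData(data.x, y_star))
        except Exception as exc:  # noqa: BLE001 - replicate skipped, logged
            failures.append(f"replicate {b}: {type(exc).__name__}: {exc}")
            continue
        yhat_b = np.asarray(pred_b(data.x), dtype=float)
        e_b = y_star - yhat_b
        e_bc = e_b - e_b.mean()
        e_star2 = rng.choice(e_bc, size=n, replace=True)
        pred_resid[b] = yhat - yhat_b + e_star2
        ok[b] = True

    n_ok = int(ok.sum())
    if n_ok < min_success_frac * B:
        raise TooManyFailuresError(
            f"only {n_ok}/{B} bootstrap replicates succeeded")
    pr = pred_resid[ok]

    order = np.argsort(data.x, kind="stable")
    bands = []
    for g in levels:
        q_lo = np.quantile(pr, (1 - g) / 2, axis=0)
        q_hi = np.quantile(pr, (1 + g) / 2, axis=0)
        bands.append(PredictionBand(
            x=data.x[order], lower=(yhat + q_lo)[order],
            upper=(yhat + q_hi)[order], level=float(g)))
    diag = BootstrapDiagnostics(requested=B, successful=n_ok, seed=seed,
                                failures=failures)
    if np.ndim(level) == 0:
        return bands[0], diag
    return bands, diag


def wild_bootstrap_breakpoint_ci(data: XYData, tau: float = 0.5,
                                 level: float = 0.95, B: int = 1000,
                                 seed: int | None = None,
                                 init: BreakpointParams | None = None,
                                 *, base_fit: QuantileFit | None = None,
                                 min_success_frac: float = 0.9,
                                 ) -> tuple[IntervalEstimate,
                                            IntervalEstimate,
                                            BootstrapDiagnostics]:
    """Wild-bootstrap percentile confidence intervals for the quantile
    fit's two breakpoints.

    The quantile model is fitted once; residuals are normalised by the
    first-order bias correction ``e_i - h_i psi_tau(e_i) / f_hat(0)``;
    each replicate multiplies their absolute values by two-point wild
    weights, rebuilds responses on the fitted curve, refits (warm start
    from the base solution) and records the breakpoints.  Interval
    limits are the empirical ``(1 -/+ level)/2`` quantiles.
    """
    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0, 1)")
    fit = base_fit if base_fit is not None else fit_pqrm(data, tau, init)
    scheme = WildScheme.from_fit(fit)
    e_tilde = np.abs(scheme.normalize(fit.residuals))
    yhat = fit.fitted

    alphas = np.empty((B, 2))
    ok = np.zeros(B, dtype=bool)
    failures: list[str] = []
    for b, rng in enumerate(_substreams(seed, B)):
        w = scheme.draw_weights(rng, data.n)
        y_star = yhat + w * e_tilde
        try:
            refit = fit_pqrm(XYData(data.x, y_star), tau,
                             init=fit.params, warm=True, exact_betas=False)
        except Exception as exc:  # noqa: BLE001 - replicate skipped, logged
            failures.append(f"replicate {b}: {type(exc).__name__}: {exc}")
            continue
        alphas[b] = refit.params.alpha
        ok[b] = True

    n_ok = int(ok.sum())
    if n_ok < min_success_frac * B:
        raise TooManyFailuresError(
            f"only {n_ok}/{B} wild-bootstrap replicates succeeded")
    a_ok = alphas[ok]
    qs = [(1 - level) / 2, (1 + level) / 2]
    ci = []
    for j, ahat in enumerate(fit.params.alpha):
        lo, hi = np.quantile(a_ok[:, j], qs)
        ci.append(IntervalEstimate(float(ahat), float(lo), float(hi),
                                   level))
    diag = BootstrapDiagnostics(requested=B, successful=n_ok, seed=seed,
                                failures=failures)
    return ci[0], ci[1], diag


# ---------------------------------------------------------------------------
# Model adapters for the prediction-band driver


class LoessModel:
    """Adapter: loess smoother with fixed span and degree."""

    def __init__(self, span: float = 0.75, degree: int = 2):
        self.span = span
        self.degree = degree

    def fit(self, data: XYData):
        from .loess import fit_loess

        return fit_loess(data, self.span, self.degree).predict


class PqrmModel:
    """Adapter: quantile fit at a fixed tau.

    The first call fits from scratch (optionally seeded by ``init``);
    subsequent calls — the bootstrap refits — warm-start from the first
    solution.
    """

    def __init__(self, tau: float = 0.5,
                 init: BreakpointParams | None = None):
        self.tau = tau
        self.init = init
        self._base: BreakpointParams | None = None

    def fit(self, data: XYData):
        if self._base is None:
            f = fit_pqrm(data, self.tau, self.init)
            self._base = f.params
        else:
            f = fit_pqrm(data, self.tau, init=self._base, warm=True,
                         exact_betas=False)
        return f.predict


class PlrmModel:
    """Adapter: least-squares fit (its band is normally parametric;
    running it through the residual bootstrap is an explicit opt-in)."""

    def __init__(self, init: BreakpointParams | None = None):
        self.init = init
        self._base: BreakpointParams | None = None

    def fit(self, data: XYData):
        from .plrm import fit_plrm

        if self._base is None:
            f = fit_plrm(data, self.init)
            self._base = f.params
        else:
            f = fit_plrm(data, init=self._base, warm=True)
        return f.predict
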