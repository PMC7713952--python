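"""Continuous two-breakpoint piecewise linear model.

The mean (or conditional-quantile) function shared by every estimator in
this package is the three-segment broken line

    m(x) = b0 + b1*x + b2*(x - a1)_+ + b3*(x - a2)_+ ,   a1 < a2,

where ``(u)_+ = max(u, 0)`` is the hinge (positive part).  The hinge
encoding makes the curve continuous at both breakpoints: the slope is
``b1`` below ``a1``, ``b1 + b2`` between the breakpoints and
``b1 + b2 + b3`` above ``a2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "XYData",
    "BreakpointParams",
    "SegmentSlopes",
    "hinge_basis",
    "piecewise_mean",
]

#: minimum sample size for a two-breakpoint fit: 6 mean parameters + 2 df
MIN_N = 8


class InvalidInputError(ValueError):
    """Raised for non-finite or structurally invalid inputs."""


@dataclass(frozen=True)
class XYData:
    """Paired predictor/response observations.

    Parameters
    ----------
    x : array-like
        Predictor (stress-gradient) values.
    y : array-like
        Response values, same length as ``x``.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1:
            raise InvalidInputError("x and y must be one-dimensional")
        if x.shape != y.shape:
            raise InvalidInputError(
                f"x and y lengths differ: {x.shape[0]} vs {y.shape[0]}"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidInputError("x and y must be finite")
        if x.shape[0] < MIN_N:
            raise InvalidInputError(
                f"need at least {MIN_N} observations for a two-breakpoint "
                f"model, got {x.shape[0]}"
            )
        if np.ptp(x) == 0:
            raise InvalidInputError("x values are all identical")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def sorted(self) -> "XYData":
        """Return a copy with observations ordered by x."""
        order = np.argsort(self.x, kind="stable")
        return XYData(self.x[order], self.y[order])


@dataclass
class BreakpointParams:
    """Parameters of the two-breakpoint piecewise linear model.

    ``beta0`` is the intercept, ``beta1`` the first-segment slope,
    ``beta2``/``beta3`` the slope changes at the first/second breakpoint,
    ``alpha1 < alpha2`` the breakpoints (x units) and ``sigma`` an
    optional residual scale (response units).
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    alpha1: float
    alpha2: float
    sigma: float | None = None

    def __post_init__(self) -> None:
        vals = [self.beta0, self.beta1, self.beta2, self.beta3,
                self.alpha1, self.alpha2]
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError("parameters must be finite")
        if not self.alpha1 < self.alpha2:
            raise InvalidInputError(
                f"breakpoints must be ordered: alpha1={self.alpha1} "
                f">= alpha2={self.alpha2}"
            )
        if self.sigma is not None and self.sigma < 0:
            raise InvalidInputError("sigma must be nonnegative")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    @property
    def alpha(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2])

    @property
    def theta(self) -> np.ndarray:
        """All six mean parameters as (beta0..beta3, alpha1, alpha2)."""
        return np.concatenate([self.beta, self.alpha])

    @classmethod
    def from_theta(cls, theta: np.ndarray,
                   sigma: float | None = None) -> "BreakpointParams":
        b0, b1, b2, b3, a1, a2 = np.asarray(theta, dtype=float)
        return cls(b0, b1, b2, b3, a1, a2, sigma)

    @property
    def segment_slopes(self) -> np.ndarray:
        """Slopes (s1, s2, s3) of the three linear segments."""
        return np.array([
            self.beta1,
            self.beta1 + self.beta2,
            self.beta1 + self.beta2 + self.beta3,
        ])


@dataclass
class SegmentSlopes:
    """Per-segment slopes with (optional) standard errors and t tests."""

    slopes: np.ndarray                       # (s1, s2, s3)
    se: np.ndarray | None = None
    t: np.ndarray | None = None
    p: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.slopes.shape != (3,):
            raise InvalidInputError("expected exactly three segment slopes")


def hinge_basis(x, alpha1: float, alpha2: float) -> np.ndarray:
    """Evaluate the hinge basis ``(1, x, (x-alpha1)_+, (x-alpha2)_+)``.

    Returns an array of shape ``x.shape + (4,)``; a scalar ``x`` yields a
    length-4 row.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("x must be finite")
    if not (np.isfinite(alpha1) and np.isfinite(alpha2)):
        raise InvalidInputError("breakpoints must be finite")
    if not alpha1 < alpha2:
        raise InvalidInputError("breakpoints must satisfy alpha1 < alpha2")
    return np.stack(
        [np.ones_like(x), x,
         np.maximum(x - alpha1, 0.0),
         np.maximum(x - alpha2, 0.0)],
        axis=-1,
    )


def piecewise_mean(x, params: BreakpointParams) -> np.ndarray | float:
    """Expected response of the two-breakpoint model at ``x``.

    Equal to the dot product of :func:`hinge_basis` with
    ``(beta0, beta1, beta2, beta3)``; continuous in ``x``.
    """
    basis = hinge_basis(x, params.alpha1, params.alpha2)
    out = basis @ params.beta
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out
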