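"""Local polynomial (loess) smoothing and breakpoint candidate screening.

The smoother fits, at every evaluation point, a weighted polynomial of
degree 1 or 2 to the ``ceil(span * n)`` nearest neighbours, with tricube
weights ``(1 - (d / d_max)^3)^3``.  This mirrors R's ``loess`` with
``surface = "direct"`` and no robustness iterations.

The smoothed curve is also used to automate what is otherwise a visual
step: proposing the number and positions of candidate breakpoints from
the curvature of the fit, which then seed the segmented mean/quantile
fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidInputError, XYData

__all__ = ["LoessFit", "CandidateBreakpoints", "fit_loess",
           "candidate_breakpoints"]


class InvalidConfigurationError(ValueError):
    """Raised when smoother settings cannot produce a valid fit."""


def _loess_predict(x_train: np.ndarray, y_train: np.ndarray,
                   x_eval: np.ndarray, span: float, degree: int,
                   ) -> np.ndarray:
    """Vectorised local polynomial regression at ``x_eval``."""
    n = x_train.shape[0]
    q = int(np.ceil(span * n))
    q = min(max(q, degree + 2), n)
    # (m, n) distances; d_max = q-th nearest neighbour distance per row
    dist = np.abs(x_eval[:, None] - x_train[None, :])
    dmax = np.partition(dist, q - 1, axis=1)[:, q - 1]
    dmax = np.where(dmax > 0, dmax, np.finfo(float).tiny)
    u = dist / dmax[:, None]
    w = np.clip(1.0 - u ** 3, 0.0, None) ** 3
    if np.any(np.sum(w > 0, axis=1) < degree + 2):
        raise InvalidConfigurationError(
            "span too small: a local neighbourhood has fewer than "
            f"{degree + 2} points with positive weight"
        )
    # centred polynomial design per evaluation point; the local intercept
    # is then the prediction
    t = x_train[None, :] - x_eval[:, None]
    cols = [np.ones_like(t)]
    for d in range(1, degree + 1):
        cols.append(t ** d)
    P = np.stack(cols, axis=-1)                     # (m, n, p)
    Pw = P * w[:, :, None]
    A = np.einsum("mnp,mnq->mpq", Pw, P)            # (m, p, p)
    b = np.einsum("mnp,n->mp", Pw, y_train)         # (m, p)
    # tiny ridge guards collinear neighbourhoods (ties in x)
    A += 1e-12 * np.trace(A, axis1=1, axis2=2)[:, None, None] \
        * np.eye(degree + 1)[None]
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    return coef[:, 0]


@dataclass
class LoessFit:
    """A fitted loess smoother with a predictor for new x."""

    data: XYData
    span: float
    degree: int
    fitted: np.ndarray

    def predict(self, x_new) -> np.ndarray | float:
        x_new_arr = np.atleast_1d(np.asarray(x_new, dtype=float))
        if not np.all(np.isfinite(x_new_arr)):
            raise InvalidInputError("prediction points must be finite")
        out = _loess_predict(self.data.x, self.data.y, x_new_arr,
                             self.span, self.degree)
        if np.isscalar(x_new) or np.ndim(x_new) == 0:
            return float(out[0])
        return out

    @property
    def residuals(self) -> np.ndarray:
        return self.data.y - self.fitted


@dataclass
class CandidateBreakpoints:
    """Proposed breakpoint locations ordered along x.

    ``incomplete`` is set when fewer well-separated curvature extrema
    than requested were found.
    """

    locations: np.ndarray
    scores: np.ndarray
    requested: int
    incomplete: bool = False

    def __len__(self) -> int:
        return self.locations.shape[0]


def fit_loess(data: XYData, span: float = 0.75, degree: int = 2) -> LoessFit:
    """Fit a loess smoother to ``data``.

    Parameters
    ----------
    data : XYData
        Observations to smooth; requires at least 10 points.
    span : float
        Fraction of observations in each local neighbourhood, in (0, 1].
    degree : int
        Local polynomial degree, 1 or 2.
    """
    if data.n < 10:
        raise InvalidInputError("loess needs at least 10 observations")
    if not 0 < span <= 1:
        raise InvalidConfigurationError("span must lie in (0, 1]")
    if degree not in (1, 2):
        raise InvalidConfigurationError("degree must be 1 or 2")
    fitted = _loess_predict(data.x, data.y, data.x, span, degree)
    return LoessFit(data=data, span=span, degree=degree, fitted=fitted)


def candidate_breakpoints(fit: LoessFit, k: int = 2,
                          grid_size: int = 512,
                          min_gap_frac: float = 0.10,
                          ) -> CandidateBreakpoints:
    """Propose up to ``k`` breakpoints from the curvature of the smoother.

    The smoothed curve is evaluated on a uniform grid over the observed
    x range; interior locations maximising the absolute central second
    difference are selected greedily, subject to a minimum separation of
    ``min_gap_frac`` times the x range.  A curve with no appreciable
    curvature yields no candidates.
    """
    if k < 1:
        raise InvalidConfigurationError("k must be at least 1")
    lo, hi = float(np.min(fit.data.x)), float(np.max(fit.data.x))
    grid = np.linspace(lo, hi, grid_size)
    smooth = fit.predict(grid)
    d2 = np.abs(np.diff(smooth, 2))                 # curvature at grid[1:-1]
    interior = grid[1:-1]
    scale = np.ptp(smooth)
    if scale == 0 or np.max(d2) <= 1e-8 * scale:
        return CandidateBreakpoints(np.empty(0), np.empty(0), k,
                                    incomplete=True)
    # the raw second difference of a k-NN smoother is jagged (discrete
    # neighbourhood changes); average it over ~4% of the grid before
    # looking for peaks
    win = max(5, grid_size // 24) | 1
    kern = np.ones(win) / win
    d2 = np.convolve(d2, kern, mode="same")
    min_gap = min_gap_frac * (hi - lo)
    # prominent local maxima of the curvature sequence are candidate
    # kinks; prominence separates two genuine kinks (curvature dips to
    # ~0 between them) from the shoulders of one smoothed kink
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(d2, prominence=0.2 * np.max(d2))
    order = peaks[np.argsort(d2[peaks])[::-1]]
    chosen: list[int] = []
    for idx in order:
        if d2[idx] <= 1e-8 * scale:
            break
        if all(abs(interior[idx] - interior[j]) >= min_gap for j in chosen):
            chosen.append(idx)
        if len(chosen) == k:
            break
    chosen_arr = np.array(sorted(chosen, key=lambda i: interior[i]),
                          dtype=int)
    return CandidateBreakpoints(
        locations=interior[chosen_arr],
        scores=d2[chosen_arr],
        requested=k,
        incomplete=len(chosen_arr) < k,
    )
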