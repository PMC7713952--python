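"""Shared knot-grid machinery for the profiled segmented fits.

Both the least-squares and the quantile fits profile out the breakpoints:
for fixed ``(alpha1, alpha2)`` the model is linear in the hinge basis, so
the outer problem is a 2-D search over admissible knot pairs.
"""

from __future__ import annotations

import numpy as np

from .core import XYData

#: minimum breakpoint separation as a fraction of the x range
MIN_GAP_FRAC = 0.05
#: minimum number of observations per segment
MIN_SEG_OBS = 3


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach a usable solution."""


class DegenerateFitError(RuntimeError):
    """Breakpoints collapsed or a segment has too few observations."""


def admissible(x: np.ndarray, a1: float, a2: float,
               min_gap: float, min_seg_obs: int = MIN_SEG_OBS) -> bool:
    """Whether a knot pair is usable for the given design."""
    lo, hi = np.min(x), np.max(x)
    if not (lo < a1 < a2 < hi):
        return False
    if a2 - a1 < min_gap:
        return False
    n1 = int(np.sum(x <= a1))
    n2 = int(np.sum((x > a1) & (x <= a2)))
    n3 = int(np.sum(x > a2))
    return min(n1, n2, n3) >= min_seg_obs


def knot_grid(data: XYData, grid_size: int) -> tuple[np.ndarray, float]:
    """Interior candidate knot locations and the minimum gap."""
    lo, hi = float(np.min(data.x)), float(np.max(data.x))
    span = hi - lo
    grid = np.linspace(lo, hi, grid_size + 2)[1:-1]
    return grid, MIN_GAP_FRAC * span
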