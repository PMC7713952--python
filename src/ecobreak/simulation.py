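"""Heteroscedastic heavy-tailed simulator and the Monte Carlo harness.

The generator draws from the two-breakpoint model with t-distributed
errors whose scale peaks in the middle of the stress gradient:

    y_i = m(x_i) + eps_i / (|x_i - g1| + g2),   eps_i ~ t(df),

so the noise standard deviation is largest near ``x = g1`` (default
0.35, close to the first breakpoint) and smallest at the edges.  The
default mean parameters are the fitted values from a real fish
community-health vs agricultural-stress relationship: b0=51.92,
b1=4.41, b2=-166.14, b3=274.00, a1=0.26, a2=0.49, with x spanning
0.0351 to 0.6698.

The harness scores the least-squares (PLRM) and median quantile (PQRM)
breakpoint estimators — bias, variance, MSE, CI coverage and width —
and the average areas of the three prediction bands (loess, parametric
PLRM, bootstrap PQRM) over replicated datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bootstrap import (LoessModel, PqrmModel, bootstrap_prediction_band,
                        PredictionBand, wild_bootstrap_breakpoint_ci)
from .core import BreakpointParams, InvalidInputError, XYData, hinge_basis, \
    piecewise_mean
from .loess import candidate_breakpoints, fit_loess
from .plrm import fit_plrm, plrm_breakpoint_ci, plrm_prediction_band
from .pqrm import fit_pqrm

__all__ = ["SimulationConfig", "generate_dataset", "default_init",
           "band_area", "summarize_estimates", "run_breakpoint_study",
           "run_band_study"]

logger = logging.getLogger(__name__)

_DEFAULT_PARAMS = BreakpointParams(
    beta0=51.92, beta1=4.41, beta2=-166.14, beta3=274.00,
    alpha1=0.26, alpha2=0.49)


@dataclass
class SimulationConfig:
    """Settings of the simulation model.

    ``gamma1``/``gamma2`` control the error-scale profile
    ``1 / (|x - gamma1| + gamma2)``; ``df`` is the t degrees of freedom
    (>= 3 so the error variance is finite and MSE meaningful).
    """

    params: BreakpointParams = field(
        default_factory=lambda: replace(_DEFAULT_PARAMS))
    x_min: float = 0.0351
    x_max: float = 0.6698
    gamma1: float = 0.35
    gamma2: float = 0.10
    df: float = 10
    n: int = 30
    replicates: int = 100
    bootstrap_B: int = 1000
    seed: int | None = None
    random_x: bool = False

    def __post_init__(self) -> None:
        if self.gamma2 <= 0:
            raise InvalidInputError("gamma2 must be positive")
        if self.df < 3:
            raise InvalidInputError(
                "df must be >= 3 for a finite error variance")
        if self.n < 8:
            raise InvalidInputError("n must be at least 8")
        if self.x_min >= self.x_max:
            raise InvalidInputError("x_min must be below x_max")


def error_scale(x, config: SimulationConfig) -> np.ndarray | float:
    """Noise scale multiplier ``1 / (|x - gamma1| + gamma2)``."""
    return 1.0 / (np.abs(np.asarray(x, dtype=float) - config.gamma1)
                  + config.gamma2)


def generate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> XYData:
    """Draw one dataset from the simulation model.

    x is an equally spaced grid spanning ``[x_min, x_max]`` by default
    (set ``random_x`` for uniform random design points); errors are iid
    t(df) scaled by :func:`error_scale`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.random_x:
        x = np.sort(rng.uniform(config.x_min, config.x_max, config.n))
    else:
        x = np.linspace(config.x_min, config.x_max, config.n)
    eps = rng.standard_t(config.df, size=config.n)
    y = piecewise_mean(x, config.params) + eps * error_scale(x, config)
    return XYData(x, y)


def default_init(data: XYData, span: float = 0.75,
                 degree: int = 2) -> BreakpointParams:
    """Initial parameter values from loess curvature screening.

    Mirrors the workflow of proposing breakpoints from the smoothed
    curve; when fewer than two curvature candidates emerge, falls back
    to the terciles of the x range.  Betas are seeded by least squares
    on the hinge basis at the proposed knots.
    """
    lo, hi = float(np.min(data.x)), float(np.max(data.x))
    try:
        cand = candidate_breakpoints(fit_loess(data, span, degree), k=2)
        locs = list(cand.locations)
    except Exception:  # noqa: BLE001 - screening is best-effort
        locs = []
    if len(locs) < 2:
        locs = [lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3]
    a1, a2 = sorted(locs[:2])
    if a2 - a1 < 0.05 * (hi - lo):
        mid = (a1 + a2) / 2
        a1 = mid - 0.05 * (hi - lo)
        a2 = mid + 0.05 * (hi - lo)
    X = hinge_basis(data.x, a1, a2)
    beta, _, _, _ = np.linalg.lstsq(X, data.y, rcond=None)
    return BreakpointParams(*beta, a1, a2)


def band_area(band: PredictionBand) -> float:
    """Trapezoidal area enclosed between the band limits."""
    return band.area


def summarize_estimates(estimates: np.ndarray, truth: float,
                        cis: list | None = None) -> dict[str, float]:
    """Bias, variance, MSE (and coverage/width from intervals) for one
    breakpoint's Monte Carlo estimates."""
    est = np.asarray(estimates, dtype=float)
    bias = float(np.mean(est) - truth)
    var = float(np.var(est, ddof=1)) if est.size > 1 else 0.0
    mse = float(np.mean((est - truth) ** 2))
    out = {"bias": bias, "var": var, "mse": mse,
           "se_bias": float(np.sqrt(var / est.size)) if est.size else np.nan,
           "se_mse": (float(np.std((est - truth) ** 2, ddof=1)
                            / np.sqrt(est.size)) if est.size > 1 else np.nan)}
    if cis is not None:
        cover = np.array([ci.lower <= truth <= ci.upper for ci in cis])
        width = np.array([ci.width for ci in cis])
        out["coverage"] = float(np.mean(cover))
        out["width"] = float(np.mean(width))
        out["se_width"] = (float(np.std(width, ddof=1) / np.sqrt(width.size))
                           if width.size > 1 else np.nan)
    return out


def _study_cells(configs, n_values, df_values, base: SimulationConfig):
    if configs is not None:
        return list(configs)
    cells = []
    for n in n_values:
        for df in df_values:
            cells.append(replace(base, n=n, df=df))
    return cells


def run_breakpoint_study(configs=None, *, n_values=(30, 150),
                         df_values=(10, 15, 20),
                         base: SimulationConfig | None = None,
                         compute_ci: bool = True,
                         methods=("PLRM", "PQRM"),
                         ci_methods=None,
                         seed: int | None = None) -> pd.DataFrame:
    """Monte Carlo comparison of the breakpoint estimators.

    For each (n, df) cell: ``replicates`` datasets are drawn; the
    selected estimators are fitted (initialised from loess candidates);
    the PLRM interval is the parametric delta-method CI and the PQRM
    interval comes from the wild bootstrap at the median.  Returns a
    tidy frame with one row per (method, breakpoint, n, df).

    ``ci_methods`` restricts which estimators get interval metrics
    (default: every fitted method when ``compute_ci`` is true); the
    per-replicate datasets depend only on the seed, not on the method
    selection.
    """
    base = base if base is not None else SimulationConfig()
    cells = _study_cells(configs, n_values, df_values, base)
    master = np.random.SeedSequence(base.seed if seed is None else seed)
    cell_seeds = master.spawn(len(cells))
    methods = tuple(methods)
    if ci_methods is None:
        ci_methods = methods if compute_ci else ()
    ci_methods = tuple(m for m in ci_methods if m in methods) \
        if compute_ci else ()

    rows = []
    for cfg, cell_ss in zip(cells, cell_seeds):
        R = cfg.replicates
        rep_seeds = cell_ss.spawn(R)
        est = {m: [] for m in methods}
        cis = {m: [] for m in methods}
        failures = 0
        for r in range(R):
            child = rep_seeds[r].spawn(2)
            data = generate_dataset(cfg, seed=child[0])
            try:
                init = default_init(data)
                if "PLRM" in methods:
                    pl = fit_plrm(data, init)
                    est["PLRM"].append(pl.params.alpha)
                    if "PLRM" in ci_methods:
                        cis["PLRM"].append(plrm_breakpoint_ci(pl, 0.95))
                if "PQRM" in methods:
                    pq = fit_pqrm(data, 0.5, init)
                    est["PQRM"].append(pq.params.alpha)
                    if "PQRM" in ci_methods:
                        ci1, ci2, _ = wild_bootstrap_breakpoint_ci(
                            data, 0.5, 0.95, B=cfg.bootstrap_B,
                            seed=child[1].generate_state(1)[0] % (2 ** 31),
                            base_fit=pq)
                        cis["PQRM"].append((ci1, ci2))
            except Exception as exc:  # noqa: BLE001 - replicate logged
                failures += 1
                logger.warning("replicate %d (n=%d, df=%g) failed: %s",
                               r, cfg.n, cfg.df, exc)
        unreliable = failures > 0.10 * R
        truth = (cfg.params.alpha1, cfg.params.alpha2)
        for method in methods:
            a = np.array(est[method])
            for j, name in enumerate(("alpha1", "alpha2")):
                ci_j = ([pair[j] for pair in cis[method]]
                        if cis[method] else None)
                m = summarize_estimates(a[:, j], truth[j], ci_j)
                rows.append({"method": method, "breakpoint": name,
                             "n": cfg.n, "df": cfg.df,
                             "replicates": R - failures,
                             "failed": failures,
                             "unreliable": unreliable, **m})
    return pd.DataFrame(rows)


def run_band_study(configs=None, *, n_values=(30, 150),
                   df_values=(10, 15, 20),
                   levels=(0.80, 0.95),
                   methods=("loess", "PLRM", "PQRM"),
                   base: SimulationConfig | None = None,
                   seed: int | None = None) -> pd.DataFrame:
    """Mean (and SE) of prediction-band areas over replicated datasets.

    Band producers: residual-bootstrap band around loess, the parametric
    t band for PLRM, and the residual-bootstrap band around the median
    quantile fit.
    """
    base = base if base is not None else SimulationConfig()
    cells = _study_cells(configs, n_values, df_values, base)
    master = np.random.SeedSequence(base.seed if seed is None else seed)
    cell_seeds = master.spawn(len(cells))
    levels = tuple(levels)

    rows = []
    for cfg, cell_ss in zip(cells, cell_seeds):
        R = cfg.replicates
        rep_seeds = cell_ss.spawn(R)
        areas = {(m, g): [] for m in methods for g in levels}
        failures = 0
        for r in range(R):
            child = rep_seeds[r].spawn(3)
            data = generate_dataset(cfg, seed=child[0])
            try:
                init = default_init(data)
                if "loess" in methods:
                    bands, _ = bootstrap_prediction_band(
                        LoessModel(), data, levels, B=cfg.bootstrap_B,
                        seed=child[1].generate_state(1)[0] % (2 ** 31))
                    for g, b in zip(levels, bands):
                        areas[("loess", g)].append(b.area)
                if "PLRM" in methods:
                    pl = fit_plrm(data, init)
                    for g in levels:
                        areas[("PLRM", g)].append(
                            plrm_prediction_band(pl, g).area)
                if "PQRM" in methods:
                    bands, _ = bootstrap_prediction_band(
                        PqrmModel(0.5, init), data, levels,
                        B=cfg.bootstrap_B,
                        seed=child[2].generate_state(1)[0] % (2 ** 31))
                    for g, b in zip(levels, bands):
                        areas[("PQRM", g)].append(b.area)
            except Exception as exc:  # noqa: BLE001 - replicate logged
                failures += 1
                logger.warning("band replicate %d (n=%d, df=%g) failed: %s",
                               r, cfg.n, cfg.df, exc)
        unreliable = failures > 0.10 * R
        for (m, g), vals in areas.items():
            v = np.asarray(vals)
            rows.append({
                "method": m, "level": g, "n": cfg.n, "df": cfg.df,
                "replicates": v.size, "failed": failures,
                "unreliable": unreliable,
                "mean_area": float(np.mean(v)) if v.size else np.nan,
                "se_area": (float(np.std(v, ddof=1) / np.sqrt(v.size))
                            if v.size > 1 else np.nan)})
    return pd.DataFrame(rows)
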