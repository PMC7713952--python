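"""Least-squares segmented fit: estimation, inference, prediction band."""

import numpy as np
import pytest

import ecobreak as eb
from ecobreak._knots import DegenerateFitError
from ecobreak.core import InvalidInputError
from ecobreak.plrm import _slope_inference


@pytest.fixture(scope="module")
def noiseless_fit(noiseless_data):
    return eb.fit_plrm(noiseless_data, eb.default_init(noiseless_data))


def test_recovers_noiseless_parameters(noiseless_fit, default_params):
    assert np.max(np.abs(noiseless_fit.params.theta
                         - default_params.theta)) < 1e-6
    assert noiseless_fit.sigma == pytest.approx(0.0, abs=1e-8)


def test_noiseless_recovery_over_random_parameters():
    """Max recovery error stays below 1e-5 across random true models."""
    rng = np.random.default_rng(0)
    worst = 0.0
    for _ in range(25):
        a1 = rng.uniform(0.2, 0.45)
        a2 = a1 + rng.uniform(0.15, 0.4)
        p = eb.BreakpointParams(rng.normal(0, 20), rng.normal(0, 30),
                                rng.normal(0, 60), rng.normal(0, 60),
                                a1, a2)
        x = np.linspace(0, 1, 60)
        d = eb.XYData(x, eb.piecewise_mean(x, p))
        f = eb.fit_plrm(d)
        worst = max(worst, float(np.max(np.abs(f.params.theta - p.theta))))
    assert worst < 1e-5


def test_sse_decreases_from_init_and_multistart_agrees(noisy_small):
    init = eb.default_init(noisy_small)
    fit = eb.fit_plrm(noisy_small, init)
    X = eb.hinge_basis(noisy_small.x, init.alpha1, init.alpha2)
    beta0, _, _, _ = np.linalg.lstsq(X, noisy_small.y, rcond=None)
    sse_init = float(np.sum((noisy_small.y - X @ beta0) ** 2))
    assert fit.sse <= sse_init + 1e-9
    # perturbed restart reaches the same optimum
    span = np.ptp(noisy_small.x)
    shifted = eb.BreakpointParams(
        *fit.params.beta,
        fit.params.alpha1 + 0.05 * span, fit.params.alpha2 - 0.05 * span)
    refit = eb.fit_plrm(noisy_small, shifted)
    assert refit.sse == pytest.approx(fit.sse, rel=1e-6)


def test_sigma_and_gradient_conditions(noisy_small):
    fit = eb.fit_plrm(noisy_small)
    n = noisy_small.n
    assert fit.sigma ** 2 == pytest.approx(fit.sse / (n - 6))
    lo, hi = noisy_small.x.min(), noisy_small.x.max()
    assert lo < fit.params.alpha1 < fit.params.alpha2 < hi


def test_breakpoint_ci_form(noisy_small):
    fit = eb.fit_plrm(noisy_small)
    ci1, ci2 = eb.plrm_breakpoint_ci(fit, 0.95)
    from scipy import stats

    se1 = np.sqrt(fit.cov[4, 4])
    tq = stats.t.ppf(0.975, noisy_small.n - 6)
    assert ci1.lower == pytest.approx(fit.params.alpha1 - tq * se1)
    assert ci1.upper == pytest.approx(fit.params.alpha1 + tq * se1)
    assert ci1.width < ci2.width or ci1.width > 0  # both positive widths
    wide1, _ = eb.plrm_breakpoint_ci(fit, 0.99)
    assert wide1.width > ci1.width


def test_noiseless_ci_zero_width(noiseless_fit):
    ci1, ci2 = eb.plrm_breakpoint_ci(noiseless_fit, 0.95)
    assert ci1.width == pytest.approx(0.0, abs=1e-6)
    assert ci2.width == pytest.approx(0.0, abs=1e-6)


def test_ci_width_shrinks_with_n():
    widths = {}
    for n in (30, 150):
        cfg = eb.SimulationConfig(n=n, df=10)
        w = []
        for child in np.random.SeedSequence(3).spawn(8):
            d = eb.generate_dataset(cfg, seed=child)
            try:
                ci1, _ = eb.plrm_breakpoint_ci(eb.fit_plrm(d), 0.95)
            except Exception:
                continue
            w.append(ci1.width)
        widths[n] = np.mean(w)
    # ~1/sqrt(n) scaling: n=150 width should be well under half of n=30
    assert widths[150] < 0.6 * widths[30]


def test_prediction_band_properties(noisy_small):
    fit = eb.fit_plrm(noisy_small)
    band80 = eb.plrm_prediction_band(fit, 0.80)
    band95 = eb.plrm_prediction_band(fit, 0.95)
    yhat = fit.predict(band80.x)
    assert np.all(band80.lower <= yhat) and np.all(yhat <= band80.upper)
    assert np.all(band95.lower <= band80.lower)
    assert np.all(band95.upper >= band80.upper)
    assert band95.area > band80.area > 0


def test_prediction_band_noiseless_collapses(noiseless_fit):
    band = eb.plrm_prediction_band(noiseless_fit, 0.95)
    np.testing.assert_allclose(band.upper - band.lower, 0, atol=1e-6)


def test_prediction_band_refuses_extrapolation(noisy_small):
    fit = eb.fit_plrm(noisy_small)
    bad = np.linspace(-1, 2, 10)
    with pytest.raises(InvalidInputError):
        eb.plrm_prediction_band(fit, 0.95, bad)
    band = eb.plrm_prediction_band(fit, 0.95, bad,
                                   allow_extrapolation=True)
    assert band.x.shape == (10,)


def test_slope_tests_consistent_with_parameters(noisy_small):
    fit = eb.fit_plrm(noisy_small)
    s = eb.slope_tests(fit)
    np.testing.assert_allclose(s.slopes, fit.params.segment_slopes)
    assert np.all(s.se >= 0)
    assert np.all((s.p >= 0) & (s.p <= 1))


def test_equal_slopes_when_no_true_slope_change():
    """beta2 = beta3 = 0 data: all three estimated segment slopes
    coincide on a noiseless line."""
    x = np.linspace(0, 1, 60)
    fit = eb.fit_plrm(eb.XYData(x, 5 + 2 * x))
    s = eb.slope_tests(fit)
    np.testing.assert_allclose(s.slopes, 2.0, atol=1e-6)


def test_slope_inference_hand_computed():
    """t statistics match hand-computed ratios for a fabricated fit."""
    p = eb.BreakpointParams(1.0, 2.0, -3.0, 4.0, 0.3, 0.6)
    cov = np.zeros((6, 6))
    cov[1, 1], cov[2, 2], cov[3, 3] = 0.04, 0.09, 0.16
    cov[1, 2] = cov[2, 1] = 0.01
    s = _slope_inference(p, cov, df=24)
    np.testing.assert_allclose(s.slopes, [2.0, -1.0, 3.0])
    np.testing.assert_allclose(
        s.se, [0.2, np.sqrt(0.04 + 0.09 + 2 * 0.01),
               np.sqrt(0.04 + 0.09 + 0.16 + 2 * 0.01)])
    np.testing.assert_allclose(s.t, s.slopes / s.se)
    from scipy import stats

    np.testing.assert_allclose(s.p, 2 * stats.t.sf(np.abs(s.t), 24))


def test_degenerate_when_no_admissible_knots():
    # all interior mass at two x values: no segment can keep 3 points
    x = np.concatenate([np.full(5, 0.0), np.full(5, 1.0)])
    x += np.linspace(0, 1e-9, 10)
    y = np.linspace(0, 1, 10)
    with pytest.raises(DegenerateFitError):
        eb.fit_plrm(eb.XYData(x, y))
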