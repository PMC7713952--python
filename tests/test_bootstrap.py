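"""Residual-bootstrap bands and the wild bootstrap for breakpoints."""

import numpy as np
import pytest

import ecobreak as eb
from ecobreak.bootstrap import DensityEstimationError, WildScheme
from ecobreak.core import InvalidInputError


class IdentityModel:
    """Interpolating 'model': fits every point exactly (zero residuals)."""

    def fit(self, data):
        x_t, y_t = data.x.copy(), data.y.copy()

        def predict(x):
            return np.interp(x, x_t, y_t)

        return predict


class LineModel:
    """Plain least-squares line; cheap and deterministic."""

    def fit(self, data):
        coef = np.polyfit(data.x, data.y, 1)

        def predict(x):
            return np.polyval(coef, x)

        return predict


@pytest.mark.parametrize("u, tau, expected", [
    (-1.0, 0.5, -0.5), (1.0, 0.5, 0.5), (-0.001, 0.9, -0.1),
    (0.0, 0.7, 0.7),
])
def test_psi_values(u, tau, expected):
    assert eb.psi(u, tau) == pytest.approx(expected)


def test_density_at_zero_normal():
    rng = np.random.default_rng(0)
    f0 = eb.density_at_zero(rng.normal(0, 1, 100_000))
    assert f0 == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.02)


def test_density_at_zero_uniform():
    rng = np.random.default_rng(1)
    f0 = eb.density_at_zero(rng.uniform(-1, 1, 100_000))
    assert f0 == pytest.approx(0.5, rel=0.05)


def test_density_at_zero_degenerate():
    with pytest.raises(DensityEstimationError):
        eb.density_at_zero(np.full(20, 1.3))


def test_wild_weights_distribution():
    rng = np.random.default_rng(2)
    for tau in (0.5, 0.8):
        scheme = WildScheme(tau=tau, leverage=np.ones(1), f0=1.0)
        w = scheme.draw_weights(rng, 10_000)
        vals = np.unique(w)
        np.testing.assert_allclose(np.sort(vals), [-2 * tau, 2 * (1 - tau)])
        # P(w = -2 tau) = tau within binomial error
        phat = np.mean(w == -2 * tau)
        assert abs(phat - tau) < 3 * np.sqrt(tau * (1 - tau) / 10_000)
    # at the median the weights are +/-1 with mean ~0
    scheme = WildScheme(tau=0.5, leverage=np.ones(1), f0=1.0)
    w = scheme.draw_weights(np.random.default_rng(3), 100_000)
    assert set(np.unique(w)) == {-1.0, 1.0}
    assert abs(w.mean()) < 0.01


def test_wild_scheme_leverage_sums_to_one(noisy_small):
    fit = eb.fit_pqrm(noisy_small, 0.5)
    scheme = WildScheme.from_fit(fit)
    assert np.sum(scheme.leverage) == pytest.approx(1.0)
    assert scheme.f0 > 0


def test_band_collapses_with_zero_residuals():
    x = np.linspace(0, 1, 20)
    d = eb.XYData(x, np.sin(x))
    band, diag = eb.bootstrap_prediction_band(IdentityModel(), d, 0.95,
                                              B=150, seed=0)
    np.testing.assert_allclose(band.upper - band.lower, 0, atol=1e-12)
    assert diag.successful == 150


def test_band_seed_reproducibility_and_nesting(noisy_small):
    b1, _ = eb.bootstrap_prediction_band(LineModel(), noisy_small, 0.80,
                                         B=200, seed=42)
    b2, _ = eb.bootstrap_prediction_band(LineModel(), noisy_small, 0.80,
                                         B=200, seed=42)
    np.testing.assert_array_equal(b1.lower, b2.lower)
    np.testing.assert_array_equal(b1.upper, b2.upper)
    b3, _ = eb.bootstrap_prediction_band(LineModel(), noisy_small, 0.80,
                                         B=200, seed=43)
    assert not np.array_equal(b1.lower, b3.lower)
    # same draws at two levels: wider level contains the narrower
    (lo_band, hi_band), _ = eb.bootstrap_prediction_band(
        LineModel(), noisy_small, [0.80, 0.95], B=200, seed=42)
    assert np.all(hi_band.lower <= lo_band.lower + 1e-12)
    assert np.all(hi_band.upper >= lo_band.upper - 1e-12)
    np.testing.assert_array_equal(lo_band.lower, b1.lower)


def test_band_fresh_point_coverage_near_nominal():
    """The 0.80 band around a correctly specified cheap model covers
    about 80% of fresh responses drawn from the same process."""
    rng = np.random.default_rng(9)
    x = np.linspace(0, 1, 60)
    covered = total = 0
    for rep in range(15):
        y = 1 + 2 * x + rng.normal(0, 0.5, 60)
        d = eb.XYData(x, y)
        band, _ = eb.bootstrap_prediction_band(LineModel(), d, 0.80,
                                               B=300, seed=rep)
        y_new = 1 + 2 * band.x + rng.normal(0, 0.5, 60)
        covered += int(np.sum((y_new >= band.lower)
                              & (y_new <= band.upper)))
        total += 60
    cov = covered / total
    assert abs(cov - 0.80) < 0.06


def test_band_input_validation(noisy_small):
    with pytest.raises(InvalidInputError):
        eb.bootstrap_prediction_band(LineModel(), noisy_small, 1.2, B=150)
    with pytest.raises(InvalidInputError):
        eb.bootstrap_prediction_band(LineModel(), noisy_small, 0.9, B=10)


def test_band_area_trapezoid():
    x = np.array([0.0, 1.0, 3.0])
    band = eb.PredictionBand(x=x, lower=np.zeros(3), upper=np.full(3, 2.0),
                             level=0.9)
    assert band.area == pytest.approx(6.0)
    # inserting a collinear grid point leaves the area unchanged
    band2 = eb.PredictionBand(x=np.array([0, 0.5, 1, 3.0]),
                              lower=np.zeros(4), upper=np.full(4, 2.0),
                              level=0.9)
    assert band2.area == pytest.approx(band.area)
    single = eb.PredictionBand(x=np.array([1.0]), lower=np.array([0.0]),
                               upper=np.array([1.0]), level=0.9)
    assert single.area == 0.0
    bad = eb.PredictionBand(x=np.array([1.0, 0.5, 2.0]),
                            lower=np.zeros(3), upper=np.ones(3), level=0.9)
    with pytest.raises(InvalidInputError):
        _ = bad.area


def test_band_area_matches_riemann_oracle():
    rng = np.random.default_rng(6)
    x = np.linspace(0, 2, 400)
    width = np.repeat(rng.uniform(0.5, 2.0, 40), 10)
    band = eb.PredictionBand(x=x, lower=np.zeros(400), upper=width,
                             level=0.5)
    riemann = float(np.sum(0.5 * (width[1:] + width[:-1]) * np.diff(x)))
    assert band.area == pytest.approx(riemann, rel=1e-12)


def test_wild_ci_reproducible_and_ordered(noisy_small):
    fit = eb.fit_pqrm(noisy_small, 0.5)
    a1, a2, diag = eb.wild_bootstrap_breakpoint_ci(
        noisy_small, 0.5, 0.95, B=120, seed=5, base_fit=fit,
        min_success_frac=0.8)
    b1, b2, _ = eb.wild_bootstrap_breakpoint_ci(
        noisy_small, 0.5, 0.95, B=120, seed=5, base_fit=fit,
        min_success_frac=0.8)
    assert (a1.lower, a1.upper) == (b1.lower, b1.upper)
    assert (a2.lower, a2.upper) == (b2.lower, b2.upper)
    assert a1.lower <= a1.upper and a2.lower <= a2.upper
    assert diag.successful <= diag.requested


def test_wild_ci_narrower_at_lower_level(noisy_large):
    fit = eb.fit_pqrm(noisy_large, 0.5)
    w95 = eb.wild_bootstrap_breakpoint_ci(
        noisy_large, 0.5, 0.95, B=120, seed=1, base_fit=fit,
        min_success_frac=0.8)
    w80 = eb.wild_bootstrap_breakpoint_ci(
        noisy_large, 0.5, 0.80, B=120, seed=1, base_fit=fit,
        min_success_frac=0.8)
    assert w80[0].width <= w95[0].width + 1e-12
    assert w80[1].width <= w95[1].width + 1e-12
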