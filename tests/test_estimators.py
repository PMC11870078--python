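"""Estimator tests: hand-computed values, closed forms, LOESS oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breathvar import (
    BreathSeries,
    Method,
    MethodSpec,
    ParameterKind,
    estimate_dispersion,
    loess_fit,
    loess_residual_sd,
    moving_sd,
    plain_sd,
    sd_bias_factor,
)
from breathvar.estimators import batch_moving_sd


def bruteforce_loess(x, y, span, degree=2):
    """Independent LOESS oracle: per-point weighted normal equations on
    the uncentred Vandermonde basis."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    q = max(degree + 2, math.ceil(span * n))
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        order = np.argsort(d, kind="stable")[:q]
        dmax = d[order[-1]]
        w = np.maximum(1.0 - (d[order] / dmax) ** 3, 0.0) ** 3
        B = np.vander(x[order], degree + 1, increasing=True)
        beta = np.linalg.solve(B.T @ (w[:, None] * B), B.T @ (w * y[order]))
        fitted[i] = sum(b * x[i] ** k for k, b in enumerate(beta))
    return fitted


def series(values, kind=ParameterKind.VT_ML):
    return BreathSeries(np.asarray(values, float), kind)


class TestPlainAndMovingSd:
    def test_plain_sd_hand_values(self):
        assert plain_sd([5, 5, 5, 5]) == 0.0
        assert plain_sd([1, 2, 3]) == pytest.approx(1.0)

    def test_plain_sd_needs_two_values(self):
        with pytest.raises(ValueError):
            plain_sd([1.0])

    def test_moving_sd_hand_values(self):
        assert moving_sd([3.0] * 20, 7) == 0.0
        # three windows of [1..5] at width 3, each with sample SD 1
        assert moving_sd([1, 2, 3, 4, 5], 3) == pytest.approx(1.0)

    def test_moving_sd_window_validation(self):
        with pytest.raises(ValueError):
            moving_sd([1, 2, 3], 5)
        with pytest.raises(ValueError):
            moving_sd([1, 2, 3], 1)

    def test_batch_matches_scalar_moving_sd(self, rng):
        Y = rng.normal(size=(5, 40))
        batch = batch_moving_sd(Y, 7)
        for row, got in zip(Y, batch):
            assert got == pytest.approx(moving_sd(row, 7), rel=1e-12)


class TestSdBiasFactor:
    def test_known_underestimation_percentages(self):
        # E[s]/sigma for normal samples; the percent bias 100*(1 - c4)
        assert 100 * (1 - sd_bias_factor(3)) == pytest.approx(11.38, abs=0.01)
        assert 100 * (1 - sd_bias_factor(5)) == pytest.approx(6.0, abs=0.02)
        assert sd_bias_factor(2) == pytest.approx(math.sqrt(2 / math.pi))

    def test_monte_carlo_cross_check_n2(self):
        rng = np.random.default_rng(99)
        s = rng.normal(size=(10**6, 2)).std(axis=1, ddof=1)
        assert s.mean() == pytest.approx(sd_bias_factor(2), abs=3e-3)

    def test_large_n_approaches_one(self):
        assert sd_bias_factor(10_000) == pytest.approx(1.0, abs=1e-4)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            sd_bias_factor(1)


class TestLoess:
    @pytest.mark.parametrize("span", [0.3, 0.75, 1.0])
    def test_quadratic_reproduced_exactly(self, span):
        x = np.arange(1.0, 41.0)
        y = 2.0 + 0.5 * x - 0.03 * x**2
        fit = loess_fit(x, y, span, degree=2)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-8)

    @pytest.mark.parametrize("span", [0.5, 0.75, 1.0])
    def test_affine_shift_leaves_residuals_unchanged(self, span, rng):
        x = np.arange(1.0, 61.0)
        y = rng.normal(size=60)
        base = loess_fit(x, y, span).residuals
        shifted = loess_fit(x, y + 3.0 - 0.7 * x, span).residuals
        np.testing.assert_allclose(shifted, base, atol=1e-8)

    @pytest.mark.parametrize("span", [0.4, 0.75, 1.0])
    @pytest.mark.parametrize("n", [8, 17, 30])
    def test_agrees_with_bruteforce_oracle(self, span, n):
        rng = np.random.default_rng(n * 100 + int(span * 100))
        x = np.arange(1.0, n + 1.0)
        y = rng.normal(size=n)
        fit = loess_fit(x, y, span)
        np.testing.assert_allclose(fit.fitted, bruteforce_loess(x, y, span),
                                   atol=1e-8)

    def test_oracle_agreement_on_irregular_abscissae(self):
        rng = np.random.default_rng(17)
        x = np.sort(rng.uniform(0, 10, size=25))
        y = rng.normal(size=25)
        fit = loess_fit(x, y, 0.6)
        np.testing.assert_allclose(fit.fitted, bruteforce_loess(x, y, 0.6),
                                   atol=1e-8)

    def test_neighborhood_size_definition(self):
        fit = loess_fit(np.arange(1.0, 41.0), np.zeros(40), 0.75)
        assert fit.neighborhood_size == 30  # ceil(0.75 * 40)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_fit([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], 1.0, degree=2)

    def test_degenerate_abscissae_named_in_error(self):
        with pytest.raises(ValueError, match="index 0"):
            loess_fit(np.ones(10), np.zeros(10), 1.0)


class TestLoessResidualSd:
    def test_constant_series_gives_zero(self):
        est = loess_residual_sd(series([5.0] * 30), span=0.75)
        assert est.value == pytest.approx(0.0, abs=1e-10)

    def test_linear_trend_does_not_change_value(self, rng):
        vals = rng.normal(790, 270, size=100)
        plain = loess_residual_sd(series(vals), 0.75).value
        trended = loess_residual_sd(series(vals + 5.0 * np.arange(100)),
                                    0.75).value
        assert trended == pytest.approx(plain, rel=1e-8)

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            loess_residual_sd(series([1.0] * 7), 0.75)


class TestDispatch:
    def test_routes_to_each_method(self):
        s = series([1.0, 2.0, 3.0] * 10)
        assert estimate_dispersion(
            series([1.0, 2.0, 3.0]), MethodSpec(Method.PLAIN_SD)
        ).value == pytest.approx(1.0)
        assert estimate_dispersion(
            series([4.0] * 30), MethodSpec(Method.MSD, window_n=7)
        ).value == 0.0
        # noiseless quadratic trend: LOESS reproduces it, residual SD ~ 0
        x = np.arange(1.0, 31.0)
        quad = series(790 + 2 * x + 0.1 * x**2)
        est = estimate_dispersion(
            quad, MethodSpec(Method.LOESS_RESID_SD, span=1.0)
        )
        assert est.value == pytest.approx(0.0, abs=1e-7)

    def test_inconsistent_specs_rejected(self):
        with pytest.raises(ValueError):
            MethodSpec(Method.LOESS_RESID_SD)  # no span
        with pytest.raises(ValueError):
            MethodSpec(Method.MSD)  # no window
        with pytest.raises(ValueError):
            MethodSpec(Method.LOESS_RESID_SD, span=1.5)


@st.composite
def value_arrays(draw):
    n = draw(st.integers(min_value=10, max_value=40))
    vals = draw(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    return np.asarray(vals)


class TestEquivariance:
    """estimate(k*y + c) = k*estimate(y) for every estimator."""

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        y=value_arrays(),
        k=st.floats(min_value=0.1, max_value=50),
        c=st.floats(min_value=-1000, max_value=1000),
    )
    def test_scale_and_translation(self, y, k, c):
        for spec in (
            MethodSpec(Method.PLAIN_SD),
            MethodSpec(Method.MSD, window_n=5),
            MethodSpec(Method.LOESS_RESID_SD, span=0.75),
        ):
            base = estimate_dispersion(series(y), spec).value
            scaled = estimate_dispersion(series(k * y + c), spec).value
            assert scaled == pytest.approx(k * base, rel=1e-8, abs=1e-8)


def test_moving_sd_window_ordering_on_flat_data():
    """Widening the MSD window shrinks the small-sample bias:
    MSD_7 < MSD_11 < MSD_19 < sigma on average over flat replicates."""
    from conftest import flat_matrix

    Y = flat_matrix("bf", 4.0, n_reps=300, seed=21)
    means = [batch_moving_sd(Y, n).mean() for n in (7, 11, 19)]
    assert means[0] < means[1] < means[2] < 4.0
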