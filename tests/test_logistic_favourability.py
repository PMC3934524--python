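import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

import bycatchclim as bc
from conftest import make_events

# published logit coefficients for the two annual bycatch models,
# used here as fixed arithmetic inputs
LEATHERBACK_COEF = (-1.376, -5.783)
LOGGERHEAD_COEF = (-0.742, 7.273)


def grid_loglik_oracle(y, x, lo=-10.0, hi=10.0, step=0.01):
    """Brute-force maximum of the Bernoulli log-likelihood over a coefficient
    grid; independent of the IRLS path."""
    a = np.arange(lo, hi + step / 2, step)
    b = np.arange(lo, hi + step / 2, step)
    best = (-np.inf, None, None)
    for i in range(0, len(a), 40):
        chunk = a[i : i + 40]
        eta = chunk[:, None, None] + b[None, :, None] * x[None, None, :]
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=2)
        j = np.unravel_index(np.argmax(ll), ll.shape)
        if ll[j] > best[0]:
            best = (float(ll[j]), float(chunk[j[0]]), float(b[j[1]]))
    return best[1], best[2]


class TestFitLogistic:
    def test_ordered_outcomes_force_positive_slope_and_separation(self):
        events = make_events([0, 0, 1, 1], [-1.0, -0.9, 0.9, 1.0])
        with pytest.warns(bc.SeparationWarning):
            fit = bc.fit_logistic(events)
        assert fit.slope > 0
        assert fit.separation_flag

    def test_symmetric_uninformative_covariate(self):
        fit = bc.fit_logistic(make_events([0, 1, 0, 1], [-1.0, -1.0, 1.0, 1.0]))
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert fit.lr_statistic == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.45, 30)
        a, b = LEATHERBACK_COEF
        y = (rng.random(30) < expit(a + b * x)).astype(int)
        fit = bc.fit_logistic(make_events(y, x))
        ga, gb = grid_loglik_oracle(y.astype(float), x)
        assert fit.converged
        assert fit.intercept == pytest.approx(ga, abs=0.02)
        assert fit.slope == pytest.approx(gb, abs=0.02)

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.45, 30)
        y = (rng.random(30) < expit(-1.0 + 2.0 * x)).astype(int)
        fit = bc.fit_logistic(make_events(y, x))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.lr_statistic == pytest.approx(ref.llr, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(bc.ValidationError):
            bc.fit_logistic(make_events([1, 1, 1], [0.1, 0.2, 0.3]))

    def test_constant_covariate_rejected(self):
        with pytest.raises(bc.ValidationError):
            bc.fit_logistic(make_events([0, 1, 0], [0.5, 0.5, 0.5]))

    def test_lr_statistic_nonnegative_identity(self):
        fit = bc.fit_logistic(make_events([0, 1, 1, 0, 1], [-0.3, 0.2, 0.5, -0.1, 0.4]))
        assert fit.lr_statistic == pytest.approx(
            2 * (fit.log_likelihood - fit.null_log_likelihood), abs=1e-10
        )
        assert fit.lr_statistic >= 0

    def test_slope_sign_recovery_rate(self):
        hits = 0
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = rng.normal(0, 1, 100)
            y = (rng.random(100) < expit(2.0 * x)).astype(int)
            if y.sum() in (0, 100):
                continue
            fit = bc.fit_logistic(make_events(y, x))
            hits += fit.slope > 0
        assert hits / 200 >= 0.95

    @given(st.floats(0.2, 5.0), st.floats(-1.0, 1.0))
    def test_lr_invariant_to_affine_covariate_rescaling(self, scale, shift):
        y = [0, 1, 1, 0, 1, 0, 1]
        x = np.array([-0.8, 0.6, 0.9, -0.2, 0.3, 0.1, -0.5])
        fit = bc.fit_logistic(make_events(y, x))
        fit2 = bc.fit_logistic(make_events(y, scale * x + shift))
        assert fit2.lr_statistic == pytest.approx(fit.lr_statistic, abs=1e-6)
        assert fit2.slope == pytest.approx(fit.slope / scale, rel=1e-4)


class TestLogitPredict:
    def test_leatherback_coefficients_at_zero(self):
        a, b = LEATHERBACK_COEF
        assert bc.logit_predict(a, b, 0.0) == pytest.approx(0.2017, abs=5e-5)

    def test_midpoint(self):
        assert bc.logit_predict(0.0, 3.7, 0.0) == 0.5

    def test_logit_zero_crossing(self):
        a, b = LOGGERHEAD_COEF
        assert bc.logit_predict(a, b, -a / b) == pytest.approx(0.5, abs=1e-12)


class TestFavourability:
    def test_neutral_case(self):
        assert bc.favourability(0.5, 5, 5) == pytest.approx(0.5)

    @given(st.integers(1, 50), st.integers(1, 50))
    def test_fixed_point_at_prevalence(self, n1, n0):
        assert bc.favourability(n1 / (n1 + n0), n1, n0) == pytest.approx(0.5, abs=1e-12)

    def test_hand_computed_value(self):
        # 0.3872 comes from a 4-d.p. rounded odds chain (0.2527 / 0.6527),
        # so agreement holds to ~2e-4, not half an ulp of the 4th decimal
        assert bc.favourability(0.2017, 4, 10) == pytest.approx(0.3872, abs=2e-4)

    def test_boundaries(self):
        assert bc.favourability(0.0, 4, 10) == 0.0
        assert bc.favourability(1.0, 4, 10) == 1.0

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(bc.ValidationError):
            bc.favourability(0.3, 4, 0)

    @given(
        st.lists(st.floats(0.001, 0.999), min_size=2, max_size=20, unique=True),
        st.integers(1, 20),
        st.integers(1, 20),
    )
    def test_strictly_increasing_in_p(self, probs, n1, n0):
        probs = sorted(probs)
        F = bc.favourability(np.array(probs), n1, n0)
        assert np.all(np.diff(F) > 0)
        assert np.all((F > 0) & (F < 1))


class TestFavourabilityCurve:
    def grid_fit(self, coef):
        return bc.LogisticFit(
            intercept=coef[0], slope=coef[1], log_likelihood=0.0,
            null_log_likelihood=0.0, lr_statistic=0.0, lr_p=1.0,
            fitted_probabilities=np.array([]),
        )

    def test_leatherback_curve_decreasing(self):
        F = bc.favourability_curve(self.grid_fit(LEATHERBACK_COEF), 4, 10,
                                   [-0.5, 0.0, 0.5])
        assert np.all(np.diff(F) < 0)

    def test_loggerhead_curve_increasing(self):
        F = bc.favourability_curve(self.grid_fit(LOGGERHEAD_COEF), 7, 7,
                                   [-0.5, 0.0, 0.5])
        assert np.all(np.diff(F) > 0)

    def test_opposite_monotone_curves_cross_once(self):
        # bisection oracle on the sign of the difference of the two curves
        grid = np.linspace(-0.5, 0.5, 2001)
        f_leather = bc.favourability_curve(self.grid_fit(LEATHERBACK_COEF), 4, 10, grid)
        f_logger = bc.favourability_curve(self.grid_fit(LOGGERHEAD_COEF), 7, 7, grid)
        sign_changes = np.sum(np.diff(np.sign(f_leather - f_logger)) != 0)
        assert sign_changes == 1

    def test_nonfinite_grid_rejected(self):
        with pytest.raises(bc.ValidationError):
            bc.favourability_curve(self.grid_fit(LOGGERHEAD_COEF), 4, 10, [0.0, np.nan])
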