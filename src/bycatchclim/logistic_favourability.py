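"""Single-covariate binary logistic regression and the favourability
transformation.

The annual bycatch events are modelled as

    P(event in year t) = expit(a + b * NAOpy_t)

fitted by maximum likelihood with Newton/IRLS iterations. The fit is plain
ML on purpose: with 14 annual observations the estimates are fragile and a
near-separated configuration sends |b| towards infinity, but silently
regularising would change the model, so separation is surfaced as a warning
flag instead.

Because logistic probabilities depend on the 1/0 frequency ratio of the
training years, the favourability transformation (Real et al.'s F) rescales
P so that F = 0.5 means conditions neither favour nor disfavour the event
regardless of prevalence:

    F = [P / (1 - P)] / [(n1 / n0) + P / (1 - P)]

with n1 and n0 the counts of event and non-event years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .event_coding import BinaryEventSeries
from .records_io import ValidationError

#: |slope| beyond which a fit is flagged as quasi-completely separated.
SEPARATION_SLOPE = 50.0


class SeparationWarning(UserWarning):
    """The covariate (quasi-)perfectly predicts the outcome."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood fit of a one-covariate logistic regression."""

    intercept: float
    slope: float
    log_likelihood: float
    null_log_likelihood: float
    lr_statistic: float  # model chi-square, df = 1
    lr_p: float
    fitted_probabilities: np.ndarray = field(repr=False)
    converged: bool = True
    iterations: int = 0
    separation_flag: bool = False

    def predict(self, covariate) -> np.ndarray:
        return logit_predict(self.intercept, self.slope, covariate)


def fit_logistic(
    series: BinaryEventSeries, tol: float = 1e-8, max_iter: int = 100
) -> LogisticFit:
    """Fit outcome ~ covariate by IRLS (Newton-Raphson on the log-likelihood).

    Convergence requires the maximum absolute coefficient change to fall
    below ``tol`` within ``max_iter`` iterations; otherwise the fit is
    returned with ``converged=False``. Raises :class:`ValidationError` if
    the outcomes are single-class or the covariate is constant.
    """
    if series.covariate is None:
        raise ValidationError("event series has no covariate attached")
    y = series.outcomes.astype(float)
    x = series.covariate.astype(float)
    if series.n1 == 0 or series.n0 == 0:
        raise ValidationError(
            "outcomes are single-class; the logistic MLE does not exist"
        )
    if np.ptp(x) == 0:
        raise ValidationError("covariate is constant")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        # Fisher information X' W X; near separation w underflows, so fall
        # back to a pseudo-inverse step rather than aborting the fit.
        xtwx = X.T @ (w[:, None] * X)
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(xtwx) @ grad
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    p = expit(X @ beta)
    ll = _bernoulli_loglik(y, p)
    p_null = y.mean()
    ll0 = _bernoulli_loglik(y, np.full_like(y, p_null))
    lr = max(2.0 * (ll - ll0), 0.0)
    separated = abs(beta[1]) > SEPARATION_SLOPE
    if separated:
        warnings.warn(
            "quasi-complete separation: |slope| diverges, estimates unreliable",
            SeparationWarning,
            stacklevel=2,
        )
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        log_likelihood=float(ll),
        null_log_likelihood=float(ll0),
        lr_statistic=float(lr),
        lr_p=float(stats.chi2.sf(lr, 1)),
        fitted_probabilities=p,
        converged=converged,
        iterations=iterations,
        separation_flag=separated,
    )


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-315, 1 - 1e-16)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def logit_predict(intercept: float, slope: float, covariate) -> np.ndarray | float:
    """P = expit(intercept + slope * covariate); saturates gracefully."""
    eta = intercept + slope * np.asarray(covariate, dtype=float)
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


def favourability(P, n1: int, n0: int):
    """Prevalence-corrected favourability of Real et al.

    F = odds(P) / (n1/n0 + odds(P)). F is a strictly increasing bijection
    of P on (0, 1) with fixed point F = 0.5 at P = n1 / (n1 + n0); the
    boundaries extend continuously to F(0) = 0 and F(1) = 1.
    """
    if n1 < 1 or n0 < 1:
        raise ValidationError("favourability needs at least one year per class")
    P = np.asarray(P, dtype=float)
    if ((P < 0) | (P > 1)).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    ratio = n1 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = P / (1.0 - P)
        F = np.where(P >= 1.0, 1.0, odds / (ratio + odds))
    return float(F) if F.ndim == 0 else F


def favourability_curve(
    fit: LogisticFit, n1: int, n0: int, covariate_grid
) -> np.ndarray:
    """Favourability evaluated over a covariate grid (for model display)."""
    grid = np.asarray(covariate_grid, dtype=float)
    if not np.isfinite(grid).all():
        raise ValidationError("covariate grid must be finite")
    return favourability(fit.predict(grid), n1, n0)
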