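"""Seeded simulation studies validating the end-to-end pipeline.

Two study designs:

* slope-sign recovery — simulate a fishery whose bycatch rate genuinely
  responds to the lagged climate index, run the full event-coding +
  logistic-fit pipeline, and score how often the fitted slope has the true
  sign;
* type-I error — the same pipeline at climate coefficient 0, scoring how
  often the likelihood-ratio test (nominal alpha) falsely rejects.

Both derive per-replicate child seeds deterministically from one master
seed, so every study is reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .event_coding import (
    annual_mean,
    lag_previous_year,
    leatherback_event,
    loggerhead_event,
)
from .logistic_favourability import SeparationWarning, fit_logistic
from .records_io import aggregate_annual, ValidationError
from .synthetic_data import SimulationConfig, simulate_fishery, simulate_monthly_index, spawn_seeds


def _study_config(coefficient: float, species: str, sets_per_year: int) -> SimulationConfig:
    base = SimulationConfig()
    coefs = dict(base.climate_coefficient)
    coefs[species] = coefficient
    return replace(base, climate_coefficient=coefs, sets_per_year=sets_per_year)


def _fit_one(config: SimulationConfig, species: str):
    """Run simulate -> event coding -> logistic fit for one replicate.

    Returns the fit, or None when the replicate is degenerate (single-class
    outcomes), which callers score conservatively.
    """
    index = simulate_monthly_index(config)
    sets = simulate_fishery(config, index)
    if species == "leatherback":
        events = leatherback_event(aggregate_annual(sets))
    else:
        events = loggerhead_event(sets)
    naopy = lag_previous_year(annual_mean(index), events.years)
    events = events.with_covariate(naopy)
    if events.n1 == 0 or events.n0 == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        return fit_logistic(events)


def slope_sign_recovery(
    coefficient: float,
    species: str,
    n_replicates: int = 100,
    sets_per_year: int = 500,
    seed: int = 0,
) -> float:
    """Fraction of replicates whose fitted slope matches the true sign.

    Degenerate replicates (single-class outcomes) count as failures.
    """
    if coefficient == 0:
        raise ValidationError("sign recovery needs a nonzero coefficient")
    hits = 0
    for child in spawn_seeds(seed, n_replicates):
        config = replace(
            _study_config(coefficient, species, sets_per_year), seed=child
        )
        fit = _fit_one(config, species)
        if fit is not None and np.sign(fit.slope) == np.sign(coefficient):
            hits += 1
    return hits / n_replicates


def type1_error_rate(
    species: str = "loggerhead",
    n_replicates: int = 200,
    sets_per_year: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the likelihood-ratio test when no climate effect
    exists; degenerate replicates count as non-rejections."""
    rejections = 0
    for child in spawn_seeds(seed, n_replicates):
        config = replace(_study_config(0.0, species, sets_per_year), seed=child)
        fit = _fit_one(config, species)
        if fit is not None and fit.lr_p < alpha:
            rejections += 1
    return rejections / n_replicates
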