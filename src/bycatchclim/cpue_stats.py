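"""CPUE computation and the effort-proportional interannual chi-square test.

CPUE (catch per unit effort) is measured in turtles per 1000 hooks. Under
the null hypothesis of a constant catch rate across years, the expected
bycatch of a year is the study-period total allocated proportionally to that
year's share of the observed effort; the chi-square goodness-of-fit statistic
against those expected counts tests for interannual differences in CPUE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records_io import ValidationError, YearRecord

SPECIES = ("loggerhead", "leatherback")

#: below this the upper chi-square tail underflows double precision; the
#: p-value is then reported as the bound "< 1e-300" rather than 0.
P_UNDERFLOW_BOUND = 1e-300


@dataclass(frozen=True)
class CpueTable:
    """Per-year and pooled CPUE (turtles per 1000 hooks) for one species."""

    species: str
    per_year: pd.Series  # index: year, values: turtles / 1000 hooks
    pooled: float  # total count / total thousands of hooks


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit result for interannual CPUE differences."""

    statistic: float
    df: int
    p_value: float
    expected: pd.Series = field(repr=False)
    p_underflowed: bool = False

    def p_display(self) -> str:
        return f"< {P_UNDERFLOW_BOUND:g}" if self.p_underflowed else f"{self.p_value:.4g}"


def _counts(records: list[YearRecord], species: str) -> pd.Series:
    if species not in SPECIES:
        raise ValidationError(f"unknown species {species!r}")
    return pd.Series(
        {r.year: getattr(r, species) for r in records}, dtype=float
    ).sort_index()


def _hooks(records: list[YearRecord]) -> pd.Series:
    return pd.Series({r.year: r.hooks_thousands for r in records}).sort_index()


def compute_cpue(records: list[YearRecord], species: str) -> CpueTable:
    """Per-year and pooled CPUE for ``species`` in turtles per 1000 hooks.

    Pooled CPUE is total count over total effort, not the mean of the annual
    values. Raises :class:`ValidationError` if any year has zero effort.
    """
    if not records:
        raise ValidationError("no records")
    hooks = _hooks(records)
    if (hooks <= 0).any():
        bad = hooks.index[hooks <= 0].tolist()
        raise ValidationError(f"zero or negative effort in year(s) {bad}")
    counts = _counts(records, species)
    return CpueTable(
        species=species,
        per_year=counts / hooks,
        pooled=float(counts.sum() / hooks.sum()),
    )


def expected_counts(records: list[YearRecord], species: str) -> pd.Series:
    """Effort-proportional expected bycatch per year.

    expected(year) = total_count * hooks(year) / total_hooks, so the expected
    counts sum to the observed total and are invariant to a uniform rescaling
    of effort.
    """
    if not records:
        raise ValidationError("no records")
    hooks = _hooks(records)
    if hooks.sum() <= 0:
        raise ValidationError("total effort must be positive")
    total = _counts(records, species).sum()
    return total * hooks / hooks.sum()


def chi_square_gof(observed: pd.Series, expected: pd.Series) -> GofResult:
    """Chi-square goodness-of-fit of observed annual counts against
    effort-proportional expected counts.

    statistic = sum (O - E)^2 / E with df = n_years - 1; the p-value is the
    upper chi-square tail. Expected values are used at full precision — no
    continuity correction and no small-count pooling.
    """
    observed, expected = observed.align(expected)
    if observed.isna().any() or expected.isna().any():
        raise ValidationError("observed and expected must cover the same years")
    if (expected <= 0).any():
        raise ValidationError("expected counts must all be positive")
    o = observed.to_numpy(dtype=float)
    e = expected.to_numpy(dtype=float)
    stat = float(np.sum((o - e) ** 2 / e))
    df = len(observed) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    underflow = df > 0 and p < P_UNDERFLOW_BOUND
    return GofResult(
        statistic=float(stat),
        df=df,
        p_value=max(p, 0.0),
        expected=expected,
        p_underflowed=underflow,
    )


def interannual_test(records: list[YearRecord], species: str) -> GofResult:
    """Convenience wrapper: expected counts + chi-square test in one call."""
    expected = expected_counts(records, species)
    observed = _counts(records, species)
    return chi_square_gof(observed, expected)
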