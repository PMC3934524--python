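"""Annual climate covariates and the two binary bycatch-event codings.

The single covariate of both bycatch models is NAOpy: the mean annual NAO
index of the year *preceding* the fishing year. Two binary outcome series
are built from the observer data:

* leatherback presence — 1 if at least one leatherback was caught that year;
* loggerhead above-average CPUE — within the swordfish-gear (LLHB) stratum
  south of 40°N, 1 if the year's CPUE exceeds the mean CPUE of the years
  with catches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .records_io import MonthlyIndexSeries, SetRecord, ValidationError, YearRecord


@dataclass(frozen=True)
class BinaryEventSeries:
    """Per-year binary outcome with its climate covariate.

    ``covariate`` is NAOpy aligned to ``years``; it may be None until
    attached with :meth:`with_covariate`. ``n1``/``n0`` count outcome-1 and
    outcome-0 years — the prevalence bookkeeping the favourability
    transformation needs.
    """

    years: tuple[int, ...]
    outcomes: np.ndarray  # 0/1 per year
    label: str
    covariate: np.ndarray | None = None

    def __post_init__(self) -> None:
        outcomes = np.asarray(self.outcomes, dtype=int)
        if not np.isin(outcomes, (0, 1)).all():
            raise ValidationError("outcomes must be 0/1")
        if len(outcomes) != len(self.years):
            raise ValidationError("outcomes and years differ in length")
        object.__setattr__(self, "outcomes", outcomes)
        if self.covariate is not None:
            cov = np.asarray(self.covariate, dtype=float)
            if len(cov) != len(self.years):
                raise ValidationError("covariate and years differ in length")
            object.__setattr__(self, "covariate", cov)

    @property
    def n1(self) -> int:
        return int(self.outcomes.sum())

    @property
    def n0(self) -> int:
        return len(self.outcomes) - self.n1

    def with_covariate(self, naopy: pd.Series) -> "BinaryEventSeries":
        """Attach a per-year covariate (e.g. from :func:`lag_previous_year`)."""
        missing = [y for y in self.years if y not in naopy.index]
        if missing:
            raise ValidationError(f"covariate missing for years {missing}")
        return replace(self, covariate=naopy.loc[list(self.years)].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "outcome": self.outcomes}
        if self.covariate is not None:
            data["covariate"] = self.covariate
        return pd.DataFrame(data)


def annual_mean(series: MonthlyIndexSeries, min_months: int = 12) -> pd.Series:
    """Unweighted mean of each calendar year's monthly index values.

    Years with fewer than ``min_months`` monthly values are dropped; the
    default of 12 keeps only complete years, since the annual NAO mean of a
    partial year would mix the index's strong seasonal cycle into the
    interannual signal.
    """
    if not series.entries:
        raise ValidationError("empty monthly index series")
    df = series.to_frame()
    grouped = df.groupby("year")["value"]
    means = grouped.mean()
    counts = grouped.size()
    return means[counts >= min_months].rename("annual_mean")


def lag_previous_year(index: pd.Series, target_years) -> pd.Series:
    """NAOpy(t) = annual index mean of year t - 1, for each target year."""
    target_years = sorted(int(y) for y in target_years)
    missing = [t for t in target_years if (t - 1) not in index.index]
    if missing:
        raise ValidationError(
            f"annual index lacks the preceding year for target year(s) {missing}"
        )
    return pd.Series(
        {t: float(index.loc[t - 1]) for t in target_years}, name="naopy"
    )


def leatherback_event(records: list[YearRecord]) -> BinaryEventSeries:
    """Presence/absence of leatherback bycatch per year (1 iff count >= 1).

    Depends only on the counts, never on effort.
    """
    recs = sorted(records, key=lambda r: r.year)
    return BinaryEventSeries(
        years=tuple(r.year for r in recs),
        outcomes=np.array([1 if r.leatherback >= 1 else 0 for r in recs]),
        label="leatherback_presence",
    )


def loggerhead_event(sets: list[SetRecord]) -> BinaryEventSeries:
    """Above-average loggerhead CPUE event in the LLHB stratum south of 40°N.

    Per-set records are filtered to LLHB gear south of 40°N; the annual CPUE
    is pooled within the stratum (total catch / total hooks in thousands).
    The threshold is the mean CPUE over the years with catches (CPUE > 0);
    a year codes 1 only if its CPUE is strictly greater than that mean, so
    ties at the threshold and zero-catch years code 0.
    """
    kept = [s for s in sets if s.gear == "LLHB" and s.south_of_40N]
    if not kept:
        raise ValidationError("no LLHB sets south of 40°N")
    df = pd.DataFrame(
        {"year": [s.year for s in kept],
         "loggerhead": [s.loggerhead for s in kept],
         "hooks": [s.hooks for s in kept]}
    )
    by_year = df.groupby("year").sum()
    cpue = by_year["loggerhead"] / (by_year["hooks"] / 1000.0)
    with_catches = cpue[cpue > 0]
    threshold = float(with_catches.mean()) if len(with_catches) else np.inf
    return BinaryEventSeries(
        years=tuple(int(y) for y in cpue.index),
        outcomes=(cpue > threshold).astype(int).to_numpy(),
        label="loggerhead_above_mean_cpue",
    )
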