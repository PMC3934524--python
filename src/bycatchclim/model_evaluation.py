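"""Calibration and discrimination metrics for the annual bycatch models:
Hosmer-Lemeshow goodness of fit, AUC, and favourability-threshold
classification rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .records_io import ValidationError


@dataclass(frozen=True)
class HLResult:
    """Hosmer-Lemeshow test result.

    ``groups`` lists (n, observed_1s, expected_1s) per probability group.
    ``df`` is (number of groups actually formed) - 2; when df <= 0 the test
    is untestable and ``p_value`` is NaN with ``untestable`` set.
    """

    statistic: float
    df: int
    p_value: float
    groups: tuple[tuple[int, int, float], ...] = field(repr=False)
    merged_groups: bool = False
    untestable: bool = False


def _group_boundaries(p_sorted: np.ndarray, n_groups: int) -> list[int]:
    """Equal-count group end-indices over sorted probabilities, with tied
    probabilities kept in the same group (a tie block never straddles a
    boundary)."""
    n = len(p_sorted)
    raw = np.linspace(0, n, n_groups + 1).round().astype(int)[1:]
    bounds: list[int] = []
    for b in raw:
        # push the boundary forward past any tie block it would split
        while 0 < b < n and p_sorted[b] == p_sorted[b - 1]:
            b += 1
        if not bounds or b > bounds[-1]:
            bounds.append(int(b))
    if bounds[-1] != n:
        bounds[-1] = n
    return bounds


def hosmer_lemeshow(outcomes, probabilities, n_groups: int = 10) -> HLResult:
    """Hosmer-Lemeshow calibration test on quantile groups of sorted
    predicted probability.

    Observations are sorted by probability and cut into ``n_groups``
    equal-count groups (ties inseparable); the statistic sums
    (O1-E1)^2/E1 + (O0-E0)^2/E0 over groups, with df = n_formed_groups - 2.
    Small samples are allowed: with n = 14 and 10 groups most groups hold
    one or two years and df = 8. A group whose expected events (or expected
    non-events) are exactly zero is merged with its neighbour and the df
    reduced, with ``merged_groups`` set.
    """
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValidationError("outcomes and probabilities differ in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("outcomes must be 0/1")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    if n_groups < 2 or len(y) < 2:
        raise ValidationError("need at least two groups and two observations")

    order = np.argsort(p, kind="stable")
    y, p = y[order], p[order]
    bounds = _group_boundaries(p, n_groups)

    groups: list[tuple[int, int, float]] = []
    start = 0
    for end in bounds:
        if end > start:
            groups.append(
                (end - start, int(y[start:end].sum()), float(p[start:end].sum()))
            )
        start = end

    # merge groups with degenerate expectations into their neighbour
    merged = False
    i = 0
    while i < len(groups) and len(groups) > 1:
        n_g, o_g, e_g = groups[i]
        if e_g == 0.0 or e_g == n_g:
            j = i - 1 if i > 0 else i + 1
            n_j, o_j, e_j = groups[j]
            groups[j] = (n_j + n_g, o_j + o_g, e_j + e_g)
            del groups[i]
            merged = True
            i = 0
        else:
            i += 1

    stat = 0.0
    for n_g, o_g, e1 in groups:
        e0 = n_g - e1
        stat += (o_g - e1) ** 2 / e1 if e1 > 0 else 0.0
        stat += ((n_g - o_g) - e0) ** 2 / e0 if e0 > 0 else 0.0

    df = len(groups) - 2
    untestable = df <= 0
    p_value = float("nan") if untestable else float(stats.chi2.sf(stat, df))
    return HLResult(
        statistic=float(stat),
        df=df,
        p_value=p_value,
        groups=tuple(groups),
        merged_groups=merged,
        untestable=untestable,
    )


def auc(outcomes, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    The proportion of (positive, negative) pairs in which the positive
    scores higher, ties counting one half — identical to trapezoidal ROC
    integration but with a simpler contract. Invariant under any strictly
    increasing transform of the scores, in particular the favourability
    transformation.
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("outcomes and scores differ in length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both outcome classes")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classification_rates(
    outcomes, favourabilities, threshold: float = 0.5
) -> tuple[float, float, float]:
    """Correct-classification rates at a favourability threshold.

    Years with F >= threshold are predicted favourable (event expected).
    Returns (rate among predicted-favourable years, rate among
    predicted-unfavourable years, overall rate); a rate over an empty
    prediction class is NaN.
    """
    y = np.asarray(outcomes, dtype=int)
    f = np.asarray(favourabilities, dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ValidationError("favourabilities must lie in [0, 1]")
    pred = (f >= threshold).astype(int)
    fav = pred == 1
    rate_fav = float((y[fav] == 1).mean()) if fav.any() else float("nan")
    rate_unf = float((y[~fav] == 0).mean()) if (~fav).any() else float("nan")
    overall = float((y == pred).mean())
    return rate_fav, rate_unf, overall
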