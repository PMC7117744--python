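"""Nonparametric day-effect analysis and descriptive diagnostics.

Covers the descriptive side of a habituation series: a tie-corrected
Friedman test on complete within-animal blocks with Dunn's many-to-one
comparisons against the first (control) day, per-day t-based confidence
intervals of the mean, and normal Q-Q diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_io import BehaviorTable
from .errors import ApplicabilityError, DegenerateDataError


@dataclass
class DunnComparison:
    day: int
    z: float
    p_adjusted: float


@dataclass
class FriedmanResult:
    """Tie-corrected Friedman statistic with Dunn's control comparisons."""

    statistic: float
    df: int
    p: float
    comparisons: list[DunnComparison]
    control_day: int
    n_complete: int
    n_dropped: int


@dataclass
class DaySummary:
    day: int
    n: int
    mean: float
    ci: tuple[float, float]


@dataclass
class QQResult:
    theoretical: np.ndarray
    ordered: np.ndarray
    correlation: float


# ---------------------------------------------------------------------------
# Friedman + Dunn
# ---------------------------------------------------------------------------

def _complete_blocks(table: BehaviorTable, response: str) -> pd.DataFrame:
    """Wide animal x day matrix of complete cases (animals seen on every day)."""
    df = table.subset(response).data
    wide = df.pivot(index="animal_id", columns="day", values="value")
    complete = wide.dropna()
    return wide, complete


def friedman_dunn(table: BehaviorTable, response: str, control_day: int = 1) -> FriedmanResult:
    """Friedman test across days with Dunn's comparisons against ``control_day``.

    Values are mid-ranked within each animal; the statistic uses the
    tie-corrected rank-sum form

        Q = (k-1) * sum_j (Rj - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

    referred to chi-square on k-1 degrees of freedom.  Dunn's z for day d is
    |mean rank(control) - mean rank(d)| / sqrt(k(k+1)/(6n)), with two-sided
    normal p multiplied by (k-1) (Bonferroni over the many-to-one family)
    and capped at 1.  Animals with missing days are dropped (complete-case).
    """
    wide, complete = _complete_blocks(table, response)
    k = wide.shape[1]
    if k < 3:
        raise ApplicabilityError(f"Friedman test needs >= 3 days, got {k}")
    n = len(complete)
    if n < 2:
        raise DegenerateDataError(f"need >= 2 complete blocks, got {n}")
    if control_day not in wide.columns:
        raise KeyError(f"control day {control_day} not observed")
    n_dropped = len(wide) - n

    values = complete.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)  # mid-ranks within animal
    rank_sums = ranks.sum(axis=0)
    denom = float((ranks ** 2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if denom == 0.0:  # every animal constant across days: no rank variation
        statistic, p = 0.0, 1.0
    else:
        statistic = float((k - 1) * np.sum((rank_sums - n * (k + 1) / 2.0) ** 2) / denom)
        p = float(stats.chi2.sf(statistic, df=k - 1))

    days = list(complete.columns)
    mean_ranks = dict(zip(days, ranks.mean(axis=0)))
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    comparisons = []
    for d in days:
        if d == control_day:
            continue
        if denom == 0.0:
            comparisons.append(DunnComparison(day=int(d), z=0.0, p_adjusted=1.0))
            continue
        z = abs(mean_ranks[control_day] - mean_ranks[d]) / se
        p_adj = min(1.0, 2.0 * float(stats.norm.sf(z)) * (k - 1))
        comparisons.append(DunnComparison(day=int(d), z=float(z), p_adjusted=max(p_adj, 1e-300)))

    return FriedmanResult(statistic=statistic, df=k - 1, p=max(p, 1e-300) if statistic > 0 else 1.0,
                          comparisons=comparisons, control_day=control_day,
                          n_complete=n, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Per-day summaries
# ---------------------------------------------------------------------------

def day_summary(table: BehaviorTable, response: str,
                level: float = 0.95) -> list[DaySummary]:
    """Mean and two-sided t-based CI of the mean, per day."""
    out = []
    for day, grp in table.subset(response).data.groupby("day"):
        v = grp["value"].to_numpy(dtype=float)
        n = len(v)
        if n < 2:
            raise DegenerateDataError(f"day {day} has fewer than 2 observations")
        m = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
        half = float(stats.t.ppf(0.5 + level / 2.0, n - 1)) * sd / np.sqrt(n)
        out.append(DaySummary(day=int(day), n=n, mean=m, ci=(m - half, m + half)))
    return out


# ---------------------------------------------------------------------------
# Normality diagnostics
# ---------------------------------------------------------------------------

def normality_qq(values) -> QQResult:
    """Normal Q-Q pairing at plotting positions (i - 0.5)/n.

    Returns ordered sample values against standard-normal quantiles plus the
    quantile-pair correlation (a scalar straightness diagnostic; 1 means the
    ordered values are exactly linear in the normal quantiles).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 3:
        raise DegenerateDataError("Q-Q diagnostic needs >= 3 values")
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs)
    corr = float(np.corrcoef(theo, v)[0, 1])
    return QQResult(theoretical=theo, ordered=v, correlation=corr)
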