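"""Temporal/geographic aggregation of matched tweets into proportion series.

Proportions are matched-tweet counts over all-COVID-tweet counts per period
and stratum (state, symptom subgroup, cohort), with 95% Wilson score
intervals.  Multi-label tweets count once in each matched subgroup's
numerator and once in the any-subgroup numerator, so subgroup proportions
may sum above the overall proportion.  Weeks are ISO weeks (Monday start),
months calendar months, all UTC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ProportionPoint",
    "TopicUsageSummary",
    "period_key",
    "aggregate_proportions",
    "wilson_ci",
    "per_user_topic_average",
    "log_topic_ratio",
]


@dataclass
class ProportionPoint:
    period_start: date
    period_end: date  # half-open [start, end)
    granularity: str  # day | week | month
    stratum: dict
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("need 0 <= numerator <= denominator")
        if not (0.0 <= self.ci_low <= self.proportion + 1e-12 and
                self.proportion - 1e-12 <= self.ci_high <= 1.0):
            raise ValueError("CI must bracket the proportion inside [0, 1]")


@dataclass
class TopicUsageSummary:
    topic_id: int
    avg_hcw: float
    avg_gen: float
    log_ratio: float
    smoothed: bool = False


def period_key(d: date | datetime, granularity: str) -> tuple[date, date]:
    """Half-open [start, end) period containing ``d`` at the granularity."""
    if isinstance(d, datetime):
        d = d.date()
    if granularity == "day":
        return d, d + timedelta(days=1)
    if granularity == "week":  # ISO week, Monday start
        start = d - timedelta(days=d.weekday())
        return start, start + timedelta(days=7)
    if granularity == "month":
        start = d.replace(day=1)
        end = (start + timedelta(days=32)).replace(day=1)
        return start, end
    raise ValueError(f"unknown granularity {granularity!r}")


def wilson_ci(k: int, n: int, level: float = 0.95, method: str = "wilson") -> tuple[float, float]:
    """Confidence interval for a binomial proportion (Wilson score by default).

    ``method='normal'`` gives the Wald interval, clipped to [0, 1], for
    comparison with normal-approximation reports.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    low, high = proportion_confint(k, n, alpha=1 - level, method=method)
    low, high = max(0.0, float(low)), min(1.0, float(high))
    # Wilson bounds are exactly 0/1 at the boundary counts; snap away rounding
    if k == 0:
        low = 0.0
    if k == n:
        high = 1.0
    return low, high


def aggregate_proportions(
    matched: pd.DataFrame,
    totals: pd.DataFrame,
    granularity: str = "week",
    strata: Sequence[str] = (),
    level: float = 0.95,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Aggregate matched tweets into per-period, per-stratum proportions.

    Parameters
    ----------
    matched
        One row per matched tweet with a ``date`` column and any stratum
        columns used (``state``, ``cohort``, ``subgroup``).  For subgroup
        strata, pass one row per (tweet, subgroup) pair — multi-label tweets
        legitimately contribute to several subgroup numerators.
    totals
        Denominator counts of all COVID tweets: a ``date`` column, a
        ``count`` column, and any *non-subgroup* stratum columns (the
        denominator does not vary by symptom subgroup).
    strata
        Stratum column names to group by, e.g. ``("subgroup",)`` or
        ``("state",)``.

    Returns a tidy frame with one row per (period, stratum) and Wilson CIs.
    Raises if any period with matches lacks a (nonzero) denominator.
    """
    matched = matched.copy()
    totals = totals.copy()
    matched["_pstart"], matched["_pend"] = zip(*matched["date"].map(lambda d: period_key(d, granularity)))
    totals["_pstart"], totals["_pend"] = zip(*totals["date"].map(lambda d: period_key(d, granularity)))

    denom_keys = ["_pstart"] + [c for c in strata if c != "subgroup"]
    denom = totals.groupby(denom_keys, as_index=False)["count"].sum()

    num_keys = ["_pstart", "_pend"] + list(strata)
    num = matched.groupby(num_keys, as_index=False).size().rename(columns={"size": "numerator"})

    merged = num.merge(denom, on=denom_keys, how="left", validate="many_to_one")
    missing = merged["count"].isna() | (merged["count"] == 0)
    if missing.any():
        bad = merged.loc[missing, "_pstart"].tolist()
        raise ValueError(f"periods with matches but no denominator: {bad}")

    # carry through denominator-only periods (zero matches) for each stratum
    # present in the numerator frame
    rows = []
    for _, r in merged.iterrows():
        k, n = int(r["numerator"]), int(r["count"])
        low, high = wilson_ci(k, n, level, ci_method)
        point = ProportionPoint(
            period_start=r["_pstart"],
            period_end=r["_pend"],
            granularity=granularity,
            stratum={c: r[c] for c in strata},
            numerator=k,
            denominator=n,
            proportion=k / n,
            ci_low=low,
            ci_high=high,
        )
        row = {
            "period_start": point.period_start,
            "period_end": point.period_end,
            "granularity": granularity,
            "numerator": k,
            "denominator": n,
            "proportion": point.proportion,
            "ci_low": low,
            "ci_high": high,
        }
        row.update(point.stratum)
        rows.append(row)
    out = pd.DataFrame(rows)
    sort_cols = ["period_start"] + list(strata)
    return out.sort_values(sort_cols, kind="stable").reset_index(drop=True)


def per_user_topic_average(
    topic_assignments: Mapping[str, int],
    tweet_users: Mapping[str, str],
    user_cohorts: Mapping[str, str],
    n_topics: int,
) -> dict[tuple[str, int], float]:
    """Mean tweets per user on each topic, by cohort.

    The denominator is the number of distinct users in the cohort, including
    users with zero tweets on a topic.
    """
    cohorts = set(user_cohorts.values())
    if not cohorts:
        raise ValueError("no cohort-labelled users")
    n_users = {c: sum(1 for v in user_cohorts.values() if v == c) for c in cohorts}
    if any(n == 0 for n in n_users.values()):
        raise ValueError("empty cohort")
    counts: dict[tuple[str, int], int] = {}
    for tweet_id, topic in topic_assignments.items():
        user = tweet_users[tweet_id]
        cohort = user_cohorts[user]
        counts[(cohort, topic)] = counts.get((cohort, topic), 0) + 1
    return {
        (c, t): counts.get((c, t), 0) / n_users[c]
        for c in cohorts
        for t in range(n_topics)
    }


def log_topic_ratio(
    avg_hcw: float, avg_gen: float, n_hcw: Optional[int] = None, n_gen: Optional[int] = None
) -> tuple[float, bool]:
    """log(avg_hcw / avg_gen), Haldane-smoothed when either average is zero.

    When either cohort's average is 0 and user counts are supplied, 0.5
    tweets are added to both cohorts' totals so the ratio stays finite; the
    second return value flags that smoothing fired.  Returns
    ``(nan, False)`` if the general-population average is zero and no user
    counts are available to smooth with.
    """
    if avg_hcw < 0 or avg_gen < 0:
        raise ValueError("averages must be non-negative")
    if avg_hcw > 0 and avg_gen > 0:
        return math.log(avg_hcw / avg_gen), False
    if n_hcw and n_gen:
        a = (avg_hcw * n_hcw + 0.5) / n_hcw
        b = (avg_gen * n_gen + 0.5) / n_gen
        return math.log(a / b), True
    return float("nan"), False
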