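"""Cohort comparison via the Wilcoxon matched-pairs signed-rank test.

The two cohorts' per-period tweet proportions (health-care workers vs the
general population, paired on ISO week by default) are compared with the
signed-rank test: zero differences are removed (Wilcoxon's method), tied
absolute differences receive midranks, and W is the sum of ranks of the
positive differences.  For ``n_effective <= 25`` the two-sided p-value is
exact — computed from the full sign-flip distribution of W, which is
identical to enumerating all 2^n sign assignments — otherwise a normal
approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSeries",
    "WilcoxonResult",
    "build_paired_series",
    "wilcoxon_signed_rank",
    "summarize_median_iqr",
    "exact_signed_rank_pvalue",
]

EXACT_LIMIT = 25  # full enumeration of sign assignments up to this n


@dataclass
class PairedSeries:
    """Aligned per-period proportions for two cohorts (x = HCW, y = general)."""

    periods: list
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.periods) == len(self.x) == len(self.y)):
            raise ValueError("periods, x, y must have equal length")
        if len(set(self.periods)) != len(self.periods):
            raise ValueError("periods must be unique")


@dataclass
class WilcoxonResult:
    W: float
    n_effective: int
    p_value: float
    method: str  # "exact" | "normal-approximation" | "degenerate"
    median_x: float = float("nan")
    iqr_x: tuple[float, float] = (float("nan"), float("nan"))
    median_y: float = float("nan")
    iqr_y: tuple[float, float] = (float("nan"), float("nan"))
    low_power: bool = False


def build_paired_series(
    hcw: pd.DataFrame, gen: pd.DataFrame, granularity: str = "week"
) -> PairedSeries:
    """Inner-join two proportion frames on period; unmatched periods dropped."""
    h = hcw[["period_start", "proportion"]].rename(columns={"proportion": "x"})
    g = gen[["period_start", "proportion"]].rename(columns={"proportion": "y"})
    merged = h.merge(g, on="period_start", how="inner").sort_values("period_start")
    n_dropped = (len(h) - len(merged)) + (len(g) - len(merged))
    if merged.empty:
        raise ValueError("no overlapping periods between cohorts")
    if n_dropped:
        logger.warning("dropped %d unpaired periods", n_dropped)
    return PairedSeries(
        periods=list(merged["period_start"]),
        x=merged["x"].to_numpy(),
        y=merged["y"].to_numpy(),
    )


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of W' over all sign assignments, on the doubled-rank grid.

    ``ranks2`` are midranks times two (integers, so ties stay exact).  The
    returned array c has c[w] = number of sign vectors with doubled-W equal
    to w; it is the coefficient list of prod_i (1 + t^{r_i}).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[: total + 1 - r]
    return counts


def exact_signed_rank_pvalue(w: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for W given the (mid)ranks of |differences|.

    Uses the sign-flip distribution (equivalent to enumerating all 2^n sign
    assignments): p = P(W' <= w_low) + P(W' >= w_high), with
    w_low = min(w, S - w), w_high = max(w, S - w), S the rank total — the
    distribution is symmetric about S/2 even under midrank ties.
    """
    ranks2 = np.rint(2 * np.asarray(ranks, dtype=float)).astype(np.int64)
    counts = _signed_rank_distribution(ranks2)
    total2 = int(ranks2.sum())
    w2 = int(round(2 * w))
    w_low = min(w2, total2 - w2)
    w_high = max(w2, total2 - w2)
    n_total = counts.sum()
    p = (counts[: w_low + 1].sum() + counts[w_high:].sum()) / n_total
    return float(min(1.0, p))


def wilcoxon_signed_rank(pairs: PairedSeries) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test on a paired series.

    Returns the statistic W (sum of positive-difference ranks after zero
    removal), the two-sided p-value, and per-cohort median/IQR summaries.
    Fewer than 6 effective pairs yields a low-power warning flag; all-zero
    differences yield a degenerate result with p = 1.
    """
    d = pairs.x - pairs.y
    nz = d != 0
    d_eff = d[nz]
    n_eff = int(nz.sum())

    med_x, iqr_x = summarize_median_iqr(pairs.x)
    med_y, iqr_y = summarize_median_iqr(pairs.y)
    summaries = dict(median_x=med_x, iqr_x=iqr_x, median_y=med_y, iqr_y=iqr_y)

    if n_eff == 0:
        return WilcoxonResult(W=0.0, n_effective=0, p_value=1.0,
                              method="degenerate", low_power=True, **summaries)

    ranks = rankdata(np.abs(d_eff))  # midranks for ties
    w = float(ranks[d_eff > 0].sum())
    low_power = n_eff < 6
    if low_power:
        logger.warning("only %d effective pairs; p-value has low power", n_eff)

    if n_eff <= EXACT_LIMIT:
        p = exact_signed_rank_pvalue(w, ranks)
        method = "exact"
    else:
        # normal approximation with tie correction and continuity correction
        mean = n_eff * (n_eff + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
        var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 - tie_term
        if var <= 0:
            p = 1.0
        else:
            z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
            p = float(min(1.0, 2 * norm.sf(abs(z))))
        method = "normal-approximation"
    return WilcoxonResult(W=w, n_effective=n_eff, p_value=p, method=method,
                          low_power=low_power, **summaries)


def summarize_median_iqr(series: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median and (Q1, Q3) with linear interpolation between order statistics."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q1), float(q3))
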