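"""Interrupted time series (ITS) segmented regression around a policy date.

The daily proportion of mental-health tweets is modelled as

    y_t = b0 + b1 * t + b2 * P_t + b3 * (t * P_t) + e_t

where t = 1..2w indexes days (1 on the first pre-policy day, window w days
on each side), and P_t is 0 before the policy date and 1 from the policy
date onward (the policy day itself counts as post).  b2 is the immediate
level change and b3 the slope change attributable to the policy.

Fitting is ordinary least squares with classical standard errors (Newey–West
available by flag), an overall F test against the intercept-only model, and
the Durbin–Watson statistic so users can judge residual autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson

logger = logging.getLogger(__name__)

__all__ = [
    "DailySeries",
    "ITSDesign",
    "ITSFit",
    "SegmentedITS",
    "build_its_design",
    "fit_segmented_ols",
    "sensitivity_analysis",
]

PARAM_NAMES = ("intercept", "time", "policy", "time_policy")


@dataclass
class DailySeries:
    """Gap-free ordered daily (date, proportion) series.

    Missing days inside the span are linearly interpolated with a logged
    warning; more than ``max_missing_fraction`` missing raises.
    """

    dates: list[date]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must align")
        if len(self.dates) < 2:
            raise ValueError("need at least 2 days")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("proportions must lie in [0, 1]")

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[date, float]], max_missing_fraction: float = 0.20
    ) -> "DailySeries":
        pairs = sorted(pairs)
        d0, d1 = pairs[0][0], pairs[-1][0]
        span = (d1 - d0).days + 1
        have = {d: v for d, v in pairs}
        n_missing = span - len(have)
        if n_missing / span > max_missing_fraction:
            raise ValueError(
                f"{n_missing}/{span} days missing (> {max_missing_fraction:.0%}); refusing to fit"
            )
        dates = [d0 + timedelta(days=i) for i in range(span)]
        vals = np.array([have.get(d, np.nan) for d in dates], dtype=float)
        if n_missing:
            logger.warning("interpolating %d missing days", n_missing)
            idx = np.arange(span)
            ok = ~np.isnan(vals)
            vals = np.interp(idx, idx[ok], vals[ok])
        return cls(dates, vals)


@dataclass
class ITSDesign:
    """Design matrix of the segmented regression: [1, t, P, t*P]."""

    y: np.ndarray
    t: np.ndarray
    policy: np.ndarray
    policy_date: date
    window_days: int
    dates: list[date] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([np.ones_like(self.t, dtype=float), self.t,
                                self.policy, self.t * self.policy])


def build_its_design(series: DailySeries, policy_date: date, window_days: int) -> ITSDesign:
    """Extract the ±window around the policy date and build the regressors.

    t runs 1..2*window_days starting on the first pre-policy day; P flips to
    1 on the policy date itself.
    """
    if window_days < 2:
        raise ValueError("window_days must be >= 2")
    start = policy_date - timedelta(days=window_days)
    end = policy_date + timedelta(days=window_days - 1)
    index = {d: i for i, d in enumerate(series.dates)}
    needed = [start + timedelta(days=i) for i in range(2 * window_days)]
    missing = [d for d in needed if d not in index]
    if missing:
        raise ValueError(f"series does not cover the window; missing dates: {missing}")
    y = np.array([series.values[index[d]] for d in needed], dtype=float)
    t = np.arange(1, 2 * window_days + 1, dtype=float)
    policy = (t > window_days).astype(float)
    return ITSDesign(y=y, t=t, policy=policy, policy_date=policy_date,
                     window_days=window_days, dates=needed)


@dataclass
class ITSFit:
    """Results of a segmented OLS fit (statsmodels-style results object)."""

    params: np.ndarray        # (b0, b1, b2, b3)
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    fvalue: float
    f_pvalue: float
    durbin_watson: float
    nobs: int
    window_days: int
    policy_date: Optional[date]
    fittedvalues: np.ndarray
    resid: np.ndarray
    cov_type: str = "nonrobust"

    @property
    def level_change(self) -> float:
        return float(self.params[2])

    @property
    def slope_change(self) -> float:
        return float(self.params[3])

    def summary(self) -> pd.DataFrame:
        """Coefficient table mirroring the standard ITS report layout."""
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "t": self.tvalues,
                "p_value": self.pvalues,
            },
            index=list(PARAM_NAMES),
        )

    def to_row(self) -> dict:
        row = {name: v for name, v in zip(PARAM_NAMES, self.params)}
        row.update({f"p_{name}": p for name, p in zip(PARAM_NAMES, self.pvalues)})
        row.update(
            f_statistic=self.fvalue, f_pvalue=self.f_pvalue,
            durbin_watson=self.durbin_watson, window_days=self.window_days,
        )
        return row


class SegmentedITS:
    """Segmented-regression ITS model for one geographic unit.

    Statsmodels-style: construct from data, call :meth:`fit` to obtain an
    :class:`ITSFit` results object.
    """

    def __init__(self, design: ITSDesign):
        self.design = design

    @classmethod
    def from_series(cls, series: DailySeries, policy_date: date, window_days: int = 15) -> "SegmentedITS":
        return cls(build_its_design(series, policy_date, window_days))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, policy_date: date,
                       window_days: int = 15) -> "SegmentedITS":
        """Build from a (date, proportion) or (date, numerator, denominator) frame."""
        df = frame.copy()
        if "proportion" not in df.columns:
            df["proportion"] = df["numerator"] / df["denominator"]
        pairs = [(d, p) for d, p in zip(pd.to_datetime(df["date"]).dt.date, df["proportion"])]
        return cls.from_series(DailySeries.from_pairs(pairs), policy_date, window_days)

    def fit(self, cov_type: str = "nonrobust", hac_maxlags: int = 3) -> ITSFit:
        X = self.design.X
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design matrix")
        model = sm.OLS(self.design.y, X)
        if cov_type == "HAC":
            res = model.fit(cov_type="HAC", cov_kwds={"maxlags": hac_maxlags})
        else:
            res = model.fit()
        # degenerate data (constant y, or exact fit) break the F ratio; fall
        # back to the sums-of-squares definition with its limits
        fvalue, f_pvalue = float(res.fvalue), float(res.f_pvalue)
        if not np.isfinite(fvalue) or fvalue < 0:
            if res.centered_tss <= 1e-30:
                fvalue, f_pvalue = 0.0, 1.0
            elif res.ssr <= 1e-30:
                fvalue, f_pvalue = np.inf, 0.0
        return ITSFit(
            params=np.asarray(res.params),
            bse=np.asarray(res.bse),
            tvalues=np.asarray(res.tvalues),
            pvalues=np.asarray(res.pvalues),
            fvalue=fvalue,
            f_pvalue=f_pvalue,
            durbin_watson=float(durbin_watson(res.resid)),
            nobs=int(res.nobs),
            window_days=self.design.window_days,
            policy_date=self.design.policy_date,
            fittedvalues=np.asarray(res.fittedvalues),
            resid=np.asarray(res.resid),
            cov_type=cov_type,
        )


def fit_segmented_ols(design: ITSDesign, cov_type: str = "nonrobust") -> ITSFit:
    """Functional wrapper: OLS on [1, t, P, t*P] with classical inference."""
    return SegmentedITS(design).fit(cov_type=cov_type)


def sensitivity_analysis(
    series: DailySeries,
    policy_date: date,
    windows: Sequence[int] = (10, 15, 20, 25),
    cov_type: str = "nonrobust",
) -> pd.DataFrame:
    """Refit the ITS at several window lengths; report sign stability.

    Returns one row per window (coefficients, p-values, F, Durbin–Watson)
    plus boolean columns flagging whether the level-change and slope-change
    signs agree with the widest-window fit.
    """
    fits = {w: SegmentedITS.from_series(series, policy_date, w).fit(cov_type=cov_type)
            for w in windows}
    rows = [fits[w].to_row() for w in windows]
    table = pd.DataFrame(rows)
    ref = fits[max(windows)]
    table["policy_sign_stable"] = [
        np.sign(f.level_change) == np.sign(ref.level_change) for f in fits.values()
    ]
    table["interaction_sign_stable"] = [
        np.sign(f.slope_change) == np.sign(ref.slope_change) for f in fits.values()
    ]
    return table
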