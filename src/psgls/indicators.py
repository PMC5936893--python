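"""Development-indicator preprocessing and bivariate screens.

Index panels (countries x years, e.g. HDI and its income, health and
education subcomponents) are reduced to one score per country: years with
too many missing countries are dropped, each surviving year is z-scored
across countries to remove broad secular trends, and the per-country mean
of the standardized years is taken.  A one-way ANOVA with country as the
factor quantifies how much of the panel variance is between countries
(eta-squared), which justifies collapsing years; bivariate OLS screens
regress the averaged scores on single predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AnovaResult",
    "OLSResult",
    "average_country_scores",
    "bivariate_ols",
    "country_anova",
    "filter_years",
    "standardize_by_year",
]


@dataclass
class AnovaResult:
    """One-way country ANOVA: F, eta2 = SS_between / SS_total, p."""

    F: float
    eta2: float
    p: float
    df_between: int
    df_within: int


@dataclass
class OLSResult:
    """Slope of a bivariate OLS with intercept, t-based 95% CI and p."""

    beta: float
    ci_low: float
    ci_high: float
    p: float
    se: float
    n: int


def filter_years(panel: pd.DataFrame, max_missing: int = 1) -> pd.DataFrame:
    """Drop year columns missing for more than ``max_missing`` countries."""
    keep = [c for c in panel.columns if panel[c].isna().sum() <= max_missing]
    if not keep:
        raise ValueError("every year exceeds the missingness threshold")
    return panel[keep]


def standardize_by_year(panel: pd.DataFrame) -> pd.DataFrame:
    """Z-score each year column across countries (n - 1 denominator)."""
    out = {}
    for col in panel.columns:
        x = panel[col]
        n = x.notna().sum()
        if n < 2:
            raise ValueError(f"year {col!r} has fewer than 2 observations")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"year {col!r} has zero spread")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=panel.index)


def average_country_scores(panel: pd.DataFrame) -> pd.Series:
    """Per-country mean over available (non-missing) standardized years."""
    if panel.isna().all(axis=1).any():
        bad = panel.index[panel.isna().all(axis=1)].tolist()
        raise ValueError(f"countries with no data in any year: {bad}")
    return panel.mean(axis=1, skipna=True)


def country_anova(panel: pd.DataFrame, standardized: bool = False) -> AnovaResult:
    """One-way ANOVA with country as factor and yearly values as replicates.

    Runs on raw yearly values by default; ``standardized`` z-scores each
    year first (the published description is ambiguous about the order of
    these steps).  Handles unbalanced panels (missing cells) by using
    each country's available years.  eta2 is the share of total sum of
    squares between countries.
    """
    if panel.shape[0] < 2 or panel.shape[1] < 2:
        raise ValueError("need at least 2 countries and 2 years")
    if standardized:
        panel = standardize_by_year(panel)
    long = panel.stack()
    grand = long.mean()
    ss_total = float(((long - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variance: ANOVA undefined")
    groups = long.groupby(level=0)
    counts = groups.size()
    means = groups.mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    k = counts.size
    n_obs = int(counts.sum())
    df_b, df_w = k - 1, n_obs - k
    if df_w <= 0:
        raise ValueError("no within-country degrees of freedom")
    if ss_within <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    return AnovaResult(F=float(f_stat), eta2=ss_between / ss_total, p=p,
                       df_between=df_b, df_within=df_w)


#: religion share columns expected in a predictor table
RELIGION_COLUMNS = ("catholic", "protestant", "orthodox", "muslim", "other")


def validate_predictor_table(table: pd.DataFrame, tol: float = 0.5) -> pd.DataFrame:
    """Check religion percentages and the communism indicator.

    Percentages must lie in [0, 100] and sum to at most 100 + tol per
    country; communism must be binary.  Returns the table unchanged (the
    "other" complement category is excluded from regression designs by
    the caller to avoid the dummy trap).
    """
    missing = [c for c in (*RELIGION_COLUMNS, "communism") if c not in table.columns]
    if missing:
        raise ValueError(f"predictor table lacks columns: {missing}")
    rel = table.loc[:, list(RELIGION_COLUMNS)]
    if ((rel < 0) | (rel > 100)).any().any():
        raise ValueError("religion percentages must lie in [0, 100]")
    over = rel.sum(axis=1) > 100.0 + tol
    if over.any():
        raise ValueError(
            f"religion percentages exceed 100 for: {table.index[over].tolist()}"
        )
    if not table["communism"].isin([0, 1]).all():
        raise ValueError("communism indicator must be 0 or 1")
    return table


def bivariate_ols(y: pd.Series | np.ndarray, x: pd.Series | np.ndarray,
                  alpha: float = 0.05) -> OLSResult:
    """OLS of y on a single predictor with intercept, pairwise-complete."""
    y = pd.Series(np.asarray(y, dtype=float))
    x = pd.Series(np.asarray(x, dtype=float))
    ok = y.notna() & x.notna()
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 paired observations")
    if float(x.std(ddof=1)) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(x.to_numpy())
    res = sm.OLS(y.to_numpy(), X).fit()
    ci = res.conf_int(alpha=alpha)[1]
    return OLSResult(beta=float(res.params[1]), ci_low=float(ci[0]),
                     ci_high=float(ci[1]), p=float(res.pvalues[1]),
                     se=float(res.bse[1]), n=int(res.nobs))
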