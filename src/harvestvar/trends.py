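"""CV-trend smoothing and environment-code regressions.

Smoothed trajectories of the rolling CV of stage abundance are fitted per
treatment with regression splines whose flexibility is indexed by degrees of
freedom; the df is chosen by AIC over the candidate set {1..10, 15, 20}, and
the curve is anchored so its value at the first defined week equals the
average initial CV (the treatments start from a common state, so their
smoothed trajectories are constrained to a common intercept).

The spline family is a *nested* truncated-power cubic basis: df=1 is a
straight line, df=2 adds a quadratic, df=3 a cubic, and each further df adds
one interior knot from a fixed coarse-to-fine (midpoint-ordered) knot
sequence. Nesting guarantees the residual sum of squares is non-increasing
in df, so the AIC comparison is a clean fit/complexity trade-off.

Environment effects are summarized with ordinary least squares of a (log)
per-replicate statistic on the numeric environment code var = 0 (constant),
1 (random), 2 (periodic), and with one-way ANOVA by environment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

log = logging.getLogger(__name__)

DEFAULT_DF_CANDIDATES: tuple[int, ...] = tuple(range(1, 11)) + (15, 20)
ENV_CODES = {"constant": 0, "random": 1, "periodic": 2}
_MAX_DF = 20


def _midpoint_order(n: int) -> list[int]:
    """Order 0..n-1 coarse-to-fine by recursive interval midpoints, so knot
    sets are nested as df grows while still spreading over the range."""
    order: list[int] = []
    queue = [(0, n - 1)]
    seen = set()
    while queue:
        lo, hi = queue.pop(0)
        mid = (lo + hi) // 2
        if mid not in seen:
            seen.add(mid)
            order.append(mid)
        if mid - 1 >= lo:
            queue.append((lo, mid - 1))
        if hi >= mid + 1:
            queue.append((mid + 1, hi))
    return order


def spline_basis(t: np.ndarray, df: int, t_max: float | None = None) -> np.ndarray:
    """Nested truncated-power cubic basis in t (t=0 at the anchor point).

    Columns: t, t^2, t^3, then (t-k)^3_+ for df-3 interior knots taken from a
    fixed midpoint-ordered sequence of 17 equally spaced knots (enough for
    df=20). Every column vanishes at t=0, which makes intercept anchoring
    exact. Bases are nested: basis(df) is the first df columns of basis(20).
    """
    if not 1 <= df <= _MAX_DF:
        raise ValueError(f"df must be in 1..{_MAX_DF}")
    t = np.asarray(t, dtype=float)
    span = t_max if t_max is not None else (t.max() if t.size else 1.0)
    if span <= 0:
        span = 1.0
    ts = t / span  # scale to ~[0, 1] for conditioning
    n_knots = _MAX_DF - 3
    knots_sorted = np.linspace(0, 1, n_knots + 2)[1:-1]
    knots = knots_sorted[_midpoint_order(n_knots)]
    cols = [ts, ts ** 2, ts ** 3]
    for k in knots[: max(0, df - 3)]:
        cols.append(np.clip(ts - k, 0, None) ** 3)
    return np.column_stack(cols[:df])


@dataclass
class TrendFit:
    """AIC-selected anchored spline fit of CV on week for one treatment."""

    chosen_df: int
    aic: dict[int, float]
    weeks: np.ndarray
    fit: np.ndarray
    se: np.ndarray
    anchor: float
    n_points: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"week": self.weeks, "fit": self.fit, "se": self.se,
                             "df": self.chosen_df})


def fit_cv_trend(cv_series_list: Sequence[pd.Series],
                 df_candidates: Sequence[int] = DEFAULT_DF_CANDIDATES,
                 anchor: float | None = None) -> TrendFit:
    """Fit the pooled CV-vs-week trend for one treatment's replicate tubes.

    Pools the (week, CV) points of all replicate rolling-CV series (missing
    edge weeks dropped), anchors the fitted value at the first defined week
    to ``anchor`` (default: the mean CV across series at that week), fits the
    anchored spline for each candidate df by least squares and keeps the df
    with minimum Gaussian AIC. Degenerate (constant) input falls back to
    df=1. Returns the fitted mean curve with pointwise 1-SE band on the
    observed week grid.
    """
    if not cv_series_list:
        raise ValueError("need at least one CV series")
    if not df_candidates:
        raise ValueError("df candidate set is empty")
    pts = []
    for s in cv_series_list:
        s = s.dropna()
        pts.append(np.column_stack([np.asarray(s.index, float), s.to_numpy(float)]))
    data = np.concatenate(pts)
    week, y = data[:, 0], data[:, 1]
    w0 = week.min()
    if anchor is None:
        anchor = float(y[week == w0].mean())
    t = week - w0
    t_max = float(t.max()) if t.max() > 0 else 1.0
    y0 = y - anchor
    n = len(y)

    results: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    aic: dict[int, float] = {}
    degenerate = float(np.var(y0)) < 1e-20
    for df in df_candidates:
        if df >= n:
            continue
        X = spline_basis(t, df, t_max)
        beta, *_ = np.linalg.lstsq(X, y0, rcond=None)
        resid = y0 - X @ beta
        rss = float(resid @ resid)
        aic[df] = n * np.log(max(rss, 1e-300) / n) + 2 * (df + 1)
        results[df] = (rss, beta, X)
    if not results:
        raise ValueError("all candidate df exceed the number of points")

    if degenerate:
        chosen = min(results)
        log.info("degenerate (constant) CV input: falling back to df=%d", chosen)
    else:
        chosen = min(aic, key=lambda d: (aic[d], d))
    rss, beta, X = results[chosen]
    sigma2 = rss / max(n - chosen, 1)
    XtX_inv = np.linalg.pinv(X.T @ X)

    grid_w = np.unique(week)
    Xg = spline_basis(grid_w - w0, chosen, t_max)
    fit = anchor + Xg @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, XtX_inv, Xg), 0) * sigma2)
    return TrendFit(chosen_df=chosen, aic=aic, weeks=grid_w, fit=fit, se=se,
                    anchor=float(anchor), n_points=n)


@dataclass(frozen=True)
class VarRegression:
    """OLS of a (transformed) per-replicate statistic on the environment code."""

    response: str
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    r_squared: float
    f_stat: float
    f_df: tuple[int, int]
    p_value: float
    n: int


def env_regression(values: Sequence[float], var_codes: Sequence[float],
                   transform: str | None = "log",
                   response_label: str = "statistic") -> VarRegression:
    """Regress per-replicate window statistics on the environment code 0/1/2.

    ``transform="log"`` fits the natural log of the statistic (the convention
    for CVs and population sizes, whose effects are multiplicative);
    ``transform=None`` fits the raw scale.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(var_codes, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(x).size < 2:
        raise ValueError("var codes are rank-deficient (single level)")
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires positive values")
        y = np.log(y)
        response_label = f"ln {response_label}"
    elif transform is not None:
        raise ValueError("transform must be 'log' or None")
    if np.ptp(y) == 0:  # flat response: slope 0, no evidence of an effect
        return VarRegression(response=response_label, intercept=float(y[0]),
                             intercept_se=0.0, slope=0.0, slope_se=0.0,
                             r_squared=0.0, f_stat=0.0,
                             f_df=(1, y.size - 2), p_value=1.0, n=int(y.size))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return VarRegression(
        response=response_label,
        intercept=float(res.params[0]), intercept_se=float(res.bse[0]),
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        r_squared=float(res.rsquared), f_stat=float(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)), p_value=float(res.f_pvalue),
        n=int(res.nobs))


@dataclass(frozen=True)
class EnvAnova:
    """One-way test of an environment effect on a per-replicate statistic.

    ``numeric_*`` treats the environment code as a linear covariate (1 df
    trend test, identical to env_regression's F); ``categorical_*`` is the
    ordinary one-way ANOVA over environment groups.
    """

    numeric_f: float
    numeric_df: tuple[int, int]
    numeric_p: float
    categorical_f: float
    categorical_df: tuple[int, int]
    categorical_p: float


def anova_by_env(groups: Mapping[float, Sequence[float]]) -> EnvAnova:
    """Test for an environment effect; ``groups`` maps var code -> values."""
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    codes = np.concatenate([[c] * len(v) for c, v in groups.items()])
    values = np.concatenate([np.asarray(v, float) for v in groups.values()])
    reg = env_regression(values, codes, transform=None)
    f_cat, p_cat = stats.f_oneway(*[np.asarray(v, float) for v in groups.values()])
    k, n = len(groups), len(values)
    if not np.isfinite(f_cat):  # identical values in every group
        f_cat, p_cat = 0.0, 1.0
    return EnvAnova(numeric_f=reg.f_stat, numeric_df=reg.f_df, numeric_p=reg.p_value,
                    categorical_f=float(f_cat), categorical_df=(k - 1, n - k),
                    categorical_p=float(p_cat))


def regression_table(stat_by_replicate: pd.DataFrame, value_col: str = "value",
                     transform: str | None = "log") -> pd.DataFrame:
    """Environment-code regressions per stage x harvest group.

    ``stat_by_replicate`` needs columns environment, harvest, stage and
    ``value_col`` (one row per replicate tube). Mirrors the layout of a
    stage-by-harvest regression table.
    """
    rows = []
    for (stage, harv), g in stat_by_replicate.groupby(["stage", "harvest"], sort=True):
        codes = g["environment"].map(ENV_CODES)
        reg = env_regression(g[value_col], codes, transform=transform,
                             response_label=value_col)
        rows.append({"stage": stage, "harvest": harv, "response": reg.response,
                     "intercept": reg.intercept, "intercept_se": reg.intercept_se,
                     "slope": reg.slope, "slope_se": reg.slope_se,
                     "r_squared": reg.r_squared, "f": reg.f_stat,
                     "df1": reg.f_df[0], "df2": reg.f_df[1],
                     "p": reg.p_value, "n": reg.n})
    return pd.DataFrame(rows)
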