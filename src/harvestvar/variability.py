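"""Population-variability statistics.

The experiment's core quantities: centered rolling coefficients of variation
of weekly stage counts, lowess detrending (so variability comparisons are
not confounded by trends in the mean), pooled window summaries per treatment
with a stratified (cluster) bootstrap and BCa confidence intervals, and
harvest-yield statistics.

The bootstrap resamples whole replicate tubes with replacement within a
treatment — tubes are the repeated-measures unit, and keeping each tube's
weeks intact preserves within-tube autocorrelation. Acceleration for the BCa
interval comes from a leave-one-tube-out jackknife.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .census_io import CensusSeries
from .exceptions import UndefinedStatisticError

log = logging.getLogger(__name__)

DEFAULT_WINDOW_WEEKS = (60, 80)
DEFAULT_LOWESS_SPAN = 0.3
DEFAULT_B = 10_000


def cv(values, ddof: int = 1) -> float:
    """Sample coefficient of variation: SD (n-1 by default) over mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise UndefinedStatisticError("CV needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(x.std(ddof=ddof) / mean)


def rolling_cv(counts: pd.Series | Sequence[float], window: int = 5) -> pd.Series:
    """Centered rolling CV: at week i, sample SD / mean of weeks i-h..i+h.

    The first and last (window-1)/2 weeks are missing. A window with zero
    mean yields a missing value (warned), not infinity.
    """
    s = counts if isinstance(counts, pd.Series) else pd.Series(np.asarray(counts, float))
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > len(s):
        raise ValueError(f"window {window} longer than series ({len(s)})")
    roll = s.rolling(window, center=True, min_periods=window)
    mean = roll.mean()
    sd = roll.std(ddof=1)
    zero = mean == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} window(s) with zero mean: CV set to missing",
                      stacklevel=2)
        mean = mean.mask(zero)
    return sd / mean


def lowess_detrend(counts: pd.Series | Sequence[float],
                   span: float = DEFAULT_LOWESS_SPAN) -> pd.Series:
    """Residuals from a lowess fit of count on week, plus the series mean.

    Adding the grand mean back preserves the level, so a CV of the detrended
    series uses the original mean as denominator.
    """
    s = counts if isinstance(counts, pd.Series) else pd.Series(np.asarray(counts, float))
    if len(s) < 10:
        raise ValueError("detrending needs at least 10 points")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    x = np.asarray(s.index, dtype=float)
    if np.any(np.isnan(x)) or len(np.unique(x)) != len(x):
        x = np.arange(len(s), dtype=float)
    smooth = lowess(s.to_numpy(float), x, frac=span, return_sorted=False)
    resid = s.to_numpy(float) - smooth
    return pd.Series(resid - resid.mean() + s.mean(), index=s.index)


# ---------------------------------------------------------------------------
# stratified (cluster) bootstrap with BCa intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapSummary:
    label: str
    estimate: float
    boot_mean: float
    ci_lo: float
    ci_hi: float
    B: int
    seed: int | None = None


def pooled_mean(arrays: Sequence[np.ndarray]) -> float:
    return float(np.mean(np.concatenate([np.asarray(a, float) for a in arrays])))


def pooled_cv(arrays: Sequence[np.ndarray]) -> float:
    return cv(np.concatenate([np.asarray(a, float) for a in arrays]))


def _bca_interval(theta_hat: float, boot: np.ndarray, jack: np.ndarray,
                  alpha: float) -> tuple[float, float]:
    if np.ptp(boot) == 0:
        return float(boot[0]), float(boot[0])
    # bias correction from the bootstrap distribution's position around theta_hat
    prop = np.clip(np.mean(boot < theta_hat), 1.0 / len(boot), 1 - 1.0 / len(boot))
    z0 = stats.norm.ppf(prop)
    # acceleration from the jackknife over strata
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    a = 0.0 if denom == 0 else (d ** 3).sum() / (6.0 * denom)
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        out.append(float(np.quantile(boot, stats.norm.cdf(adj))))
    return out[0], out[1]


def stratified_bootstrap(replicates: Sequence[np.ndarray],
                         statistic: Callable[[Sequence[np.ndarray]], float],
                         B: int = DEFAULT_B, seed: int | None = None,
                         alpha: float = 0.05, label: str = "statistic",
                         max_redraws: int = 100) -> BootstrapSummary:
    """Cluster bootstrap over replicate tubes with a BCa 95% CI.

    Tubes are resampled with replacement; ``statistic`` receives the list of
    (whole) resampled tube series. A resample on which the statistic is
    undefined is redrawn and logged.
    """
    reps = [np.asarray(r, dtype=float) for r in replicates]
    n = len(reps)
    if n < 2:
        raise ValueError("need at least two replicate tubes")
    if B < 1:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    theta_hat = statistic(reps)

    boot = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                boot[b] = statistic([reps[i] for i in idx])
                break
            except UndefinedStatisticError:
                redraws += 1
                if redraws > max_redraws:
                    raise
    if redraws:
        log.info("redrew %d bootstrap resample(s) with undefined statistic", redraws)

    jack = np.array([statistic(reps[:i] + reps[i + 1:]) for i in range(n)])
    lo, hi = _bca_interval(theta_hat, boot, jack, alpha)
    return BootstrapSummary(label=label, estimate=float(theta_hat),
                            boot_mean=float(boot.mean()), ci_lo=lo, ci_hi=hi,
                            B=B, seed=seed)


# ---------------------------------------------------------------------------
# treatment-level window summaries and yields
# ---------------------------------------------------------------------------

def _treatments(series_list: Sequence[CensusSeries]) -> dict[tuple[str, str], list[CensusSeries]]:
    groups: dict[tuple[str, str], list[CensusSeries]] = {}
    for s in series_list:
        groups.setdefault((s.environment, s.harvest), []).append(s)
    return groups


def window_summary(series_list: Sequence[CensusSeries],
                   weeks: tuple[int, int] = DEFAULT_WINDOW_WEEKS,
                   stage: str = "adults", statistic: str = "cv",
                   detrend: bool = True, span: float = DEFAULT_LOWESS_SPAN,
                   B: int = DEFAULT_B, seed: int | None = None) -> pd.DataFrame:
    """Per-treatment bootstrap summary of a stage statistic over a week window.

    For ``statistic="cv"`` each tube's window series is first lowess-detrended
    (level preserved) when ``detrend`` is on; the statistic is then computed
    on the weeks pooled across the resampled tubes. Returns one row per
    environment x harvest treatment with the point estimate, bootstrap mean
    and BCa 95% CI.
    """
    if statistic not in ("mean", "cv"):
        raise ValueError("statistic must be 'mean' or 'cv'")
    if weeks[0] > weeks[1]:
        raise ValueError("weeks must be an inclusive (start, end) range")
    stat_fn = pooled_mean if statistic == "mean" else pooled_cv
    groups = sorted(_treatments(series_list).items())
    child_seqs = np.random.SeedSequence(seed).spawn(len(groups)) if seed is not None else None
    rows = []
    for gi, ((env, harv), tubes) in enumerate(groups):
        if len(tubes) < 2:
            raise ValueError(f"treatment ({env}, {harv}) has fewer than 2 replicates")
        arrays = []
        for t in tubes:
            w = t.window(weeks)
            if w.empty:
                raise ValueError(f"tube {t.tube} has no data in weeks {weeks}")
            vals = (w[list(("eggs", "juveniles", "adults"))].sum(axis=1)
                    if stage == "total" else w[stage]).to_numpy(float)
            if detrend and statistic == "cv":
                vals = lowess_detrend(pd.Series(vals), span=span).to_numpy()
            arrays.append(vals)
        sub_seed = (int(child_seqs[gi].generate_state(1)[0] % (2 ** 31))
                    if child_seqs is not None else None)
        summary = stratified_bootstrap(arrays, stat_fn, B=B, seed=sub_seed,
                                       label=f"{env}/{harv} {stage} {statistic}")
        rows.append({"environment": env, "harvest": harv, "stage": stage,
                     "statistic": statistic, "n_replicates": len(tubes),
                     "estimate": summary.estimate, "boot_mean": summary.boot_mean,
                     "ci_lo": summary.ci_lo, "ci_hi": summary.ci_hi,
                     "B": B, "seed": sub_seed})
    return pd.DataFrame(rows)


def bootstrap_contrast(replicates_a: Sequence[np.ndarray],
                       replicates_b: Sequence[np.ndarray],
                       statistic: Callable[[Sequence[np.ndarray]], float],
                       B: int = DEFAULT_B, seed: int | None = None,
                       alpha: float = 0.05, label: str = "contrast") -> BootstrapSummary:
    """Cluster-bootstrap CI for the difference statistic(b) - statistic(a).

    Tubes are resampled with replacement independently within each group; the
    percentile interval of the difference tests whether the two treatments
    differ (0 outside the CI = significant at ``alpha``).
    """
    a = [np.asarray(r, float) for r in replicates_a]
    b = [np.asarray(r, float) for r in replicates_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    rng = np.random.default_rng(seed)
    point = statistic(b) - statistic(a)
    deltas = np.empty(B)
    for i in range(B):
        ia = rng.integers(0, len(a), size=len(a))
        ib = rng.integers(0, len(b), size=len(b))
        deltas[i] = statistic([b[j] for j in ib]) - statistic([a[j] for j in ia])
    lo, hi = np.percentile(deltas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapSummary(label=label, estimate=float(point),
                            boot_mean=float(deltas.mean()), ci_lo=float(lo),
                            ci_hi=float(hi), B=B, seed=seed)


def harvest_contrast(series_list: Sequence[CensusSeries], environment: str,
                     harvest: str = "proportional",
                     weeks: tuple[int, int] = DEFAULT_WINDOW_WEEKS,
                     stage: str = "adults", detrend: bool = True,
                     span: float = DEFAULT_LOWESS_SPAN, B: int = DEFAULT_B,
                     seed: int | None = None) -> BootstrapSummary:
    """CI for the harvested-minus-control difference in windowed stage CV
    within one environment (the harvest-effect test of the headline result)."""
    def arrays(harv):
        tubes = [s for s in series_list
                 if s.environment == environment and s.harvest == harv]
        out = []
        for t in tubes:
            vals = t.window(weeks)[stage].to_numpy(float)
            if detrend:
                vals = lowess_detrend(pd.Series(vals), span=span).to_numpy()
            out.append(vals)
        return out
    return bootstrap_contrast(arrays("none"), arrays(harvest), pooled_cv,
                              B=B, seed=seed,
                              label=f"{environment}: {harvest} - none {stage} cv")


@dataclass(frozen=True)
class YieldSummary:
    """Harvest yield over a window: cumulative adults removed (mean across
    replicate tubes, with 2 SE) and the temporal CV of weekly takes
    (per-replicate CV averaged, with 2 SE)."""

    total: float
    total_2se: float
    cv: float
    cv_2se: float
    n_replicates: int


def yield_stats(series_list: Sequence[CensusSeries],
                weeks: tuple[int, int] = (13, 83)) -> YieldSummary:
    """Yield statistics for a set of replicate tubes of one harvest treatment."""
    totals, cvs = [], []
    for s in series_list:
        takes = s.window(weeks)["harvested"].to_numpy(float)
        if takes.size == 0:
            raise ValueError(f"tube {s.tube} has no weeks in {weeks}")
        totals.append(takes.sum())
        if np.all(takes == 0):
            raise UndefinedStatisticError(
                f"tube {s.tube}: yield CV undefined for all-zero takes")
        cvs.append(cv(takes))
    totals, cvs = np.asarray(totals), np.asarray(cvs)
    n = len(totals)
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return YieldSummary(total=float(totals.mean()), total_2se=2 * sem(totals),
                        cv=float(cvs.mean()), cv_2se=2 * sem(cvs), n_replicates=n)


def realized_harvest_rate(series_list: Sequence[CensusSeries],
                          weeks: tuple[int, int] = DEFAULT_WINDOW_WEEKS) -> tuple[float, float]:
    """Mean weekly fraction of the adult census removed, with SD across
    tube-weeks (harvested / pre-harvest adults, weeks with adults present)."""
    fracs = []
    for s in series_list:
        w = s.window(weeks)
        mask = w["adults"] > 0
        fracs.append((w.loc[mask, "harvested"] / w.loc[mask, "adults"]).to_numpy())
    allf = np.concatenate(fracs)
    return float(allf.mean()), float(allf.std(ddof=1))
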