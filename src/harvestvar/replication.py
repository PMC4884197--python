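"""End-to-end week-window analysis driver.

Runs the full downstream pipeline on a census collection (deposited or
simulated): per-treatment bootstrap CV and mean-abundance summaries for the
focal week window, environment-code regression tables for log CV and log
abundance (one row per stage x harvest group), yield statistics per harvest
treatment, and — when a size table is supplied — group size summaries.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .census_io import CensusSeries, STAGES
from .exceptions import UndefinedStatisticError
from .sizes import size_summary
from .trends import regression_table
from .variability import (DEFAULT_WINDOW_WEEKS, cv, lowess_detrend,
                          window_summary, yield_stats)


def per_replicate_stats(series_list: Sequence[CensusSeries],
                        weeks: tuple[int, int] = DEFAULT_WINDOW_WEEKS,
                        detrend: bool = True, span: float = 0.3) -> pd.DataFrame:
    """Per-tube window statistics: mean abundance and (detrended) CV for each
    stage and the total population. One row per tube x stage."""
    rows = []
    for s in series_list:
        w = s.window(weeks)
        for stage in (*STAGES, "total"):
            vals = (w[list(STAGES)].sum(axis=1) if stage == "total"
                    else w[stage]).to_numpy(float)
            series = pd.Series(vals)
            det = lowess_detrend(series, span=span).to_numpy() if detrend else vals
            rows.append({"tube": s.tube, "environment": s.environment,
                         "harvest": s.harvest, "stage": stage,
                         "mean": float(vals.mean()), "cv": cv(det)})
    return pd.DataFrame(rows)


def replicate_analysis(series_list: Sequence[CensusSeries],
                       sizes: pd.DataFrame | None = None,
                       weeks: tuple[int, int] = DEFAULT_WINDOW_WEEKS,
                       harvest_window: tuple[int, int] = (13, 83),
                       B: int = 2000, seed: int | None = 0) -> dict:
    """Run the whole window analysis; returns a dict of result tables.

    Keys: ``cv_summary`` and ``mean_summary`` (bootstrap treatment summaries
    per stage), ``cv_regressions`` and ``abundance_regressions``
    (environment-code OLS per stage x harvest, log scale), ``yields`` (per
    harvest treatment), and optionally ``size_summary``.
    """
    cv_frames, mean_frames = [], []
    for stage in (*STAGES, "total"):
        cv_frames.append(window_summary(series_list, weeks=weeks, stage=stage,
                                        statistic="cv", detrend=True, B=B, seed=seed))
        mean_frames.append(window_summary(series_list, weeks=weeks, stage=stage,
                                          statistic="mean", detrend=False, B=B, seed=seed))
    per_rep = per_replicate_stats(series_list, weeks=weeks)

    # regressions need >= 2 environments per harvest group
    def regressable(df, col):
        keep = df.groupby("harvest")["environment"].transform("nunique") >= 2
        return df[keep & (df[col] > 0)]

    out = {
        "per_replicate": per_rep,
        "cv_summary": pd.concat(cv_frames, ignore_index=True),
        "mean_summary": pd.concat(mean_frames, ignore_index=True),
        "cv_regressions": regression_table(regressable(per_rep, "cv"), "cv"),
        "abundance_regressions": regression_table(regressable(per_rep, "mean"), "mean"),
    }

    yield_rows = []
    for harv in sorted({s.harvest for s in series_list} - {"none"}):
        for env in sorted({s.environment for s in series_list if s.harvest == harv}):
            tubes = [s for s in series_list
                     if s.harvest == harv and s.environment == env]
            try:
                ys = yield_stats(tubes, weeks=harvest_window)
            except UndefinedStatisticError:
                continue
            yield_rows.append({"environment": env, "harvest": harv,
                               "total": ys.total, "total_2se": ys.total_2se,
                               "cv": ys.cv, "cv_2se": ys.cv_2se,
                               "n_replicates": ys.n_replicates})
    out["yields"] = pd.DataFrame(yield_rows)

    if sizes is not None:
        by = [c for c in ("environment", "harvest", "stage") if c in sizes.columns]
        out["size_summary"] = size_summary(sizes, by=by)
    return out
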