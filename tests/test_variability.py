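import numpy as np
import pandas as pd
import pytest

from harvestvar.exceptions import UndefinedStatisticError
from harvestvar.census_io import CensusSeries
from harvestvar.variability import (BootstrapSummary, bootstrap_contrast, cv,
                                    harvest_contrast, lowess_detrend,
                                    pooled_cv, pooled_mean, rolling_cv,
                                    stratified_bootstrap, window_summary,
                                    yield_stats)


def brute_force_rolling_cv(x, window):
    """Independent oracle: recompute every window from scratch."""
    h = (window - 1) // 2
    out = np.full(len(x), np.nan)
    for i in range(h, len(x) - h):
        w = np.asarray(x[i - h:i + h + 1], dtype=float)
        out[i] = w.std(ddof=1) / w.mean()
    return out


class TestRollingCV:
    def test_constant_series_is_zero(self):
        out = rolling_cv(pd.Series([50.0] * 10), window=5)
        assert np.allclose(out.dropna(), 0.0)

    def test_hand_computed_centre_value(self):
        out = rolling_cv(pd.Series([1.0, 2, 3, 4, 5]), window=5)
        # sd(1..5)=1.5811, mean 3
        assert out.iloc[2] == pytest.approx(0.527, abs=5e-4)
        assert out.iloc[[0, 1, 3, 4]].isna().all()

    def test_edges_missing(self):
        out = rolling_cv(pd.Series(np.arange(1.0, 21.0)), window=5)
        assert out.iloc[:2].isna().all() and out.iloc[-2:].isna().all()
        assert out.iloc[2:-2].notna().all()

    def test_matches_brute_force_oracle(self, rng):
        x = rng.gamma(5, 20, size=200)
        for window in (5, 9, 21):
            ours = rolling_cv(pd.Series(x), window=window).to_numpy()
            oracle = brute_force_rolling_cv(x, window)
            np.testing.assert_allclose(ours, oracle, rtol=1e-12, equal_nan=True)

    def test_scale_invariance(self, rng):
        x = rng.gamma(5, 20, size=60)
        a = rolling_cv(pd.Series(x), 5).dropna()
        b = rolling_cv(pd.Series(17.3 * x), 5).dropna()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            rolling_cv(pd.Series(np.ones(20)), window=4)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            rolling_cv(pd.Series(np.ones(4)), window=5)

    def test_zero_mean_window_is_missing_with_warning(self):
        x = pd.Series([1.0, 0, 0, 0, 0, 0, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="zero mean"):
            out = rolling_cv(x, 5)
        assert out.iloc[3].item() != out.iloc[3].item()  # NaN


class TestLowessDetrend:
    def test_linear_series_flattened(self):
        y = pd.Series(3.0 * np.arange(40) + 10)
        resid = lowess_detrend(y, span=0.4) - y.mean()
        slope = np.polyfit(np.arange(40), resid, 1)[0]
        assert abs(slope) < 1e-6 * y.mean()

    def test_mean_preserved(self, rng):
        y = pd.Series(rng.gamma(4, 50, size=50))
        out = lowess_detrend(y)
        assert out.mean() == pytest.approx(y.mean(), rel=1e-9)

    def test_recovers_trend_free_cv(self, rng):
        # AR(1) noise around a level, plus a strong (level-preserving) linear
        # trend: detrending should give back the trend-free CV within 10%
        n, trials = 100, 20
        ratios = []
        for _ in range(trials):
            eps = np.empty(n)
            eps[0] = rng.normal()
            for i in range(1, n):
                eps[i] = 0.3 * eps[i - 1] + rng.normal()
            base = 200 + 12 * eps
            trended = base + np.linspace(-75, 75, n)
            ratios.append(cv(lowess_detrend(pd.Series(trended), span=0.3)) / cv(base))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            lowess_detrend(pd.Series(np.arange(5.0)))


class TestStratifiedBootstrap:
    def test_identical_replicates_degenerate_ci(self):
        reps = [np.full(20, 7.0)] * 6
        s = stratified_bootstrap(reps, pooled_mean, B=200, seed=1)
        assert s.estimate == s.ci_lo == s.ci_hi == 7.0

    def test_reproducible_under_seed(self, rng):
        reps = [rng.gamma(5, 10, 20) for _ in range(6)]
        a = stratified_bootstrap(reps, pooled_cv, B=500, seed=42)
        b = stratified_bootstrap(reps, pooled_cv, B=500, seed=42)
        assert a == b

    def test_bca_close_to_percentile_for_symmetric_statistic(self, rng):
        # mean of many balanced strata: bias and acceleration ~ 0
        reps = [rng.normal(50, 5, 25) for _ in range(30)]
        s = stratified_bootstrap(reps, pooled_mean, B=4000, seed=2)
        boot = []
        rng2 = np.random.default_rng(7)
        for _ in range(4000):
            idx = rng2.integers(0, 30, 30)
            boot.append(pooled_mean([reps[i] for i in idx]))
        lo, hi = np.percentile(boot, [2.5, 97.5])
        mc_err = 3 * np.std(boot) / np.sqrt(len(boot)) + 0.1
        assert s.ci_lo == pytest.approx(lo, abs=mc_err)
        assert s.ci_hi == pytest.approx(hi, abs=mc_err)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            stratified_bootstrap([np.ones(5)], pooled_mean, B=10, seed=0)


def _make_series(env, harv, tube, counts, harvested=None):
    n = len(counts)
    df = pd.DataFrame({"week": np.arange(1, n + 1), "eggs": 0, "juveniles": 0,
                       "adults": counts,
                       "harvested": harvested if harvested is not None else 0})
    return CensusSeries(tube=tube, environment=env, harvest=harv, counts=df)


class TestWindowSummary:
    def test_identical_constant_replicates_zero_cv(self):
        series = [_make_series("constant", "none", f"t{i}", [120] * 30)
                  for i in range(4)]
        out = window_summary(series, weeks=(5, 25), stage="adults",
                             statistic="cv", detrend=False, B=200, seed=0)
        row = out.iloc[0]
        assert row["estimate"] == 0.0
        assert row["ci_hi"] - row["ci_lo"] == 0.0

    def test_mean_statistic_matches_pooled_mean(self, rng):
        counts = [rng.integers(100, 200, 30) for _ in range(4)]
        series = [_make_series("random", "none", f"t{i}", c)
                  for i, c in enumerate(counts)]
        out = window_summary(series, weeks=(1, 30), stage="adults",
                             statistic="mean", detrend=False, B=100, seed=0)
        expected = np.mean(np.concatenate(counts))
        assert out.iloc[0]["estimate"] == pytest.approx(expected)

    def test_one_row_per_treatment(self, small_experiment):
        out = window_summary(small_experiment, weeks=(10, 28), B=100, seed=0)
        assert len(out) == 7
        assert (out["ci_lo"] <= out["ci_hi"]).all()

    def test_bootstrap_coverage_with_strata(self, rng):
        # cluster bootstrap CI for the pooled mean over 30 AR(1) strata
        trials, covered = 60, 0
        truth = 100.0
        for _ in range(trials):
            reps = []
            for _ in range(30):
                e = np.empty(15)
                e[0] = rng.normal()
                for i in range(1, 15):
                    e[i] = 0.5 * e[i - 1] + rng.normal()
                reps.append(truth + 8 * e)
            s = stratified_bootstrap(reps, pooled_mean, B=400,
                                     seed=int(rng.integers(2 ** 31)))
            covered += s.ci_lo <= truth <= s.ci_hi
        assert covered / trials > 0.85  # smoke-level; full calibration elsewhere


class TestContrast:
    def test_contrast_zero_for_identical_groups(self):
        reps = [np.full(20, 5.0) + i * 0 for i in range(4)]
        s = bootstrap_contrast(reps, reps, pooled_mean, B=100, seed=0)
        assert s.estimate == 0.0 and s.ci_lo == s.ci_hi == 0.0

    def test_detects_known_shift(self, rng):
        a = [rng.normal(100, 5, 20) for _ in range(6)]
        b = [rng.normal(130, 5, 20) for _ in range(6)]
        s = bootstrap_contrast(a, b, pooled_mean, B=500, seed=1)
        assert s.ci_lo > 0

    def test_harvest_contrast_labels(self, headline_experiment):
        s = harvest_contrast(headline_experiment, "constant", B=100, seed=0)
        assert "constant" in s.label


class TestYieldStats:
    def test_constant_takes(self):
        series = [_make_series("random", "proportional", "t1", [100] * 10,
                               harvested=[4] * 10)]
        ys = yield_stats(series, weeks=(1, 10))
        assert ys.total == 40 and ys.cv == 0.0

    def test_hand_computed_cv(self):
        series = [_make_series("random", "proportional", "t1", [100, 100],
                               harvested=[0, 10])]
        ys = yield_stats(series, weeks=(1, 2))
        assert ys.total == 10
        assert ys.cv == pytest.approx(1.414, abs=1e-3)

    def test_all_zero_takes_undefined(self):
        series = [_make_series("constant", "none", "t1", [100] * 10)]
        with pytest.raises(UndefinedStatisticError):
            yield_stats(series, weeks=(1, 10))
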