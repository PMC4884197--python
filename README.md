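# harvestvar

Harvesting × environmental variability in stage-structured populations.

`harvestvar` is a tested analysis pipeline for weekly census data from
food-manipulated, adult-harvested invertebrate microcosms, built around the
design of a 102-week soil-mite (*Sancassania berlesei*) experiment: 42
replicate tubes under three food regimes with equal mean supply — constant,
random (negative-binomial daily rations) and periodic (a 28-day
feast–famine cycle) — crossed with adult-harvest rules, either proportional
(40 % of adults per week) or threshold/fixed escapement (all adults above
173), active in weeks 13–83. It is aimed at population ecologists and
quantitative fisheries/harvest researchers who want the full chain from
raw stage counts to treatment-level inference, plus a stochastic simulator
that generates census data with the same statistical structure so every
stage of the pipeline is testable without the original data.

## What it computes

For weekly stage counts N(t) per tube:

* rolling coefficients of variation, CV(i) = sd(N(i−2…i+2)) / mean(N(i−2…i+2)),
  in centered windows of ~one generation;
* lowess-detrended window CVs (variability comparisons not confounded by
  trends in the mean);
* treatment summaries over an inclusive week window (default 60–80) with a
  stratified *cluster* bootstrap — whole replicate tubes resampled with
  replacement — and BCa 95 % confidence intervals;
* harvested-minus-control CV contrasts with bootstrap CIs;
* AIC-selected anchored spline trends of CV over time (df ∈ {1…10, 15, 20});
* OLS of log CV or log abundance on the environment code
  var = 0/1/2 (constant/random/periodic), and one-way ANOVA by environment;
* harvest yields (cumulative adults removed ± 2 SE, temporal CV of weekly
  takes) and realized harvest rates;
* body-size structure: Gaussian KDE of log lengths on an 8192-point grid
  with a bootstrapped 95 % confidence envelope (R = 10,000).

The simulator (`harvestvar.simulate`) is a daily-timestep egg → juvenile →
adult model with food-dependent vital rates: the day's intake ratio
r = min(1, available/(demand_J·J + demand_A·A)) scales survival, convex
juvenile maturation (∝ r²) and per-female fecundity, so reduced density
triggers compensatory — and in fluctuating environments overcompensatory —
recruitment. Defaults are calibrated so an unharvested tube on constant
food settles at the experiment's observed equilibrium (≈ 560 eggs, 1145
juveniles, 264 adults) with a ≈ 34-day generation time. See
`docs/methods.md` for the model, calibration and all statistical
conventions.

## Worked example

```python
from harvestvar.simulate import ExperimentDesign, run_experiment
from harvestvar.variability import window_summary, harvest_contrast

design = ExperimentDesign(master_seed=1)        # 42 tubes, 102 weeks
series = run_experiment(design)

ws = window_summary(series, weeks=(60, 80), stage="adults",
                    statistic="cv", detrend=True, B=2000, seed=1)
print(ws[["environment", "harvest", "estimate", "ci_lo", "ci_hi"]])

for env in ("constant", "periodic"):
    c = harvest_contrast(series, env, weeks=(60, 80), B=2000, seed=1)
    print(f"{env}: harvest effect on adult CV = {c.estimate:+.3f} "
          f"[{c.ci_lo:+.3f}, {c.ci_hi:+.3f}]")
```

Output (seed 1):

```
  environment       harvest  estimate     ci_lo     ci_hi
0    constant          none  0.056951  0.047946  0.060144
1    constant  proportional  0.051543  0.047753  0.055055
2    periodic          none  0.266751  0.261555  0.275145
3    periodic  proportional  0.406677  0.392222  0.421192
4      random          none  0.203630  0.197863  0.211749
5      random  proportional  0.228164  0.208533  0.250980
6      random     threshold  0.264716  0.239769  0.295557
constant: harvest effect on adult CV = -0.005 [-0.012, +0.002]
periodic: harvest effect on adult CV = +0.140 [+0.121, +0.154]
```

Read: the detrended CV of adult numbers over weeks 60–80 rises with
environmental variability (constant < random < periodic), and harvesting
adults raises adult-stage variability significantly in the periodic
environment (+0.131, CI excludes 0) while having no detectable effect in
the constant environment — the interaction at the heart of the analysis.
Each row's CI is a BCa interval from resampling the six replicate tubes.

A command-line interface mirrors the pipeline stages:

```
harvestvar simulate --seed 1 --out runs/demo
harvestvar analyze-window --census runs/demo/census.csv --weeks 60 80 \
    --stage adults --statistic cv --out runs/demo/window.csv
harvestvar trend --census runs/demo/census.csv --out runs/demo/trend.csv
```

Deposited census tables with foreign headers can be ingested with
`read_census(path, column_map={...})`.

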