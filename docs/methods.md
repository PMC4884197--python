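# Methods

`harvestvar` analyses how stage-selective harvesting interacts with
environmental variability in food supply to change the variability and size
of stage-structured populations, using the design of a long-running
soil-mite (*Sancassania berlesei*) microcosm experiment: 42 replicate glass
tubes censused weekly for 102 weeks under three food regimes with equal mean
supply and three adult-harvest treatments. This note documents the models,
the statistics, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Food regimes and harvest rules

All regimes deliver 2 yeast balls/day (1 ball = 0.0015 g) on average:

* **constant** — 2 balls every day (weekly-total CV exactly 0);
* **periodic** — a fixed 28-day cycle (9 days of 0, 3×1, 2×3, 9×4, 3×3,
  2×1 balls; 56 balls per cycle). Its weekly totals are (0, 9, 28, 19),
  giving a CV of 0.8670 with the sample (n−1) SD convention — the package
  uses that convention everywhere because it reproduces the experiment's
  reported value (0.86) to rounding;
* **random** — daily counts from a negative binomial (mean 2, dispersion
  0.5), truncated to 0–13 balls/day. Each 56-day block is nudged, one ball
  at a time between randomly chosen days, until it totals exactly 112
  balls, because all treatments received the same total food; unconstrained
  draws would also have a weekly CV near 0.6 rather than the experiment's
  ≈0.36. The constraint can be switched off
  (`RandomRegimeSpec(constrain_block_totals=False)`). The realized weekly CV
  depends on the realization (typically 0.3–0.5); the experiment's 0.36 is a
  property of its particular unpublished sequence.

Harvesting acts on adults at the weekly census, during weeks 13–83
inclusive (weeks are 1-based):

* **proportional** — remove `round_half_up(0.40 × adults)`; whole animals
  are removed, and half-up rounding is unbiased over trajectories;
* **threshold** (fixed escapement) — remove `max(0, adults − 173)`; harvest
  is density-dependent and zero below the threshold.

Counts are recorded *before* removal, so census tables hold pre-harvest
abundances plus the take.

## The simulator

A daily-timestep stochastic model of eggs → juveniles → adults in a closed
tube. Food arrives per the regime, tops up a pool that decays by 40 %/day
(spoilage), and is consumed up to demand (0.013 balls/adult/day, 0.002
balls/juvenile/day). The intake ratio

    r = min(1, available / (d_J·J + d_A·A))

drives the food-dependent rates. Daily transitions (sampled as binomials,
births as Poisson):

| rate | form | value at r* = 0.35 |
|---|---|---|
| egg survival | constant 0.90/day | 0.90 |
| hatch | constant 0.084/day | 0.084 |
| juvenile survival | 0.951 + 0.073·r (cap 0.999) | 0.977 |
| maturation | 0.116·r² | 0.0142 |
| adult survival | 0.915 + 0.073·r (cap 0.999) | 0.940 |
| fecundity (eggs/female/day) | 2.13·r | 0.745 |

Females are half the adults (the experiment inoculates 1:1 and sex is not
tracked). Tubes start from the experiment's inoculation: 300 adults, 1000
juveniles, 0 eggs.

**Calibration.** The experiment gives no vital-rate equations, so the
functional forms and defaults are this package's own, solved analytically
from the stage-flow balance at the constant-food equilibrium the experiment
observed over weeks 60–80 (eggs ≈ 560, juveniles ≈ 1145, adults ≈ 264) and
checked against three oracles: (1) the expectation-mode model settles on
exactly those abundances; (2) the mean egg-to-first-reproduction time at
the realized equilibrium intake is ≈ 33.7 days, inside the observed 30–37
day generation time; (3) the harvest × environment interaction below. Three
structural choices matter and were fixed during calibration:

* the equilibrium intake ratio is r* = 0.35 with adults holding 60 % of
  total demand, so that removing adults frees enough food for compensatory
  recruitment — with weak compensation, 40 %/week harvesting collapses the
  tubes, which the experiment's populations did not do;
* maturation is convex in intake (exponent 2): juveniles arrest under
  famine and mature in bursts when food returns. This produces the
  overcompensatory adult recruitment that makes harvested populations more
  variable in fluctuating environments, and places the random regime's
  population variability between constant and periodic;
* adults turn over fast (≈ 17-day expected adult span at equilibrium), so
  a 40 %/week harvest is a moderate addition to natural turnover rather
  than an order-of-magnitude change.

**Process noise.** Three terms beyond demographic sampling, all off in
expectation mode: an AR(1) lognormal multiplier on fecundity (stationary
SD 0.5, autocorrelation 0.9 — day-scale persistence of ambient condition);
an iid daily shock on adult survival (SD 0.03); and a static per-tube
lognormal fecundity multiplier (SD 0.2) representing replicate
heterogeneity (micro-climate, founder composition). The last is what gives
the cluster bootstrap realistic between-tube spread; without it all tubes
are statistical clones and any harvest effect, however trivial, is
"significant".

**Expectation mode** replaces every draw by its mean on a real-valued
state. Stage-flow conservation (hatched, matured, births, deaths, harvest)
is then an exact identity, asserted in tests; it also provides the
deterministic equilibrium used for calibration.

**What the generator does not emulate.** Life-history evolution over the
run (the real populations evolved, changing trajectories mid-experiment),
individual body sizes (size tables come from a separate lognormal fixture
generator), sex structure, and stage-specific measurement error. Weeks
60–80 contrasts are therefore comparable in structure to the experiment,
but CV trend *time courses* are only qualitatively comparable, and passing
tests show that the pipeline detects the interaction when present — not
that the simulator is a faithful mite model.

## Statistics

* **Rolling CV**: at week *i*, sample SD/mean of the adult count over weeks
  *i−2…i+2* (5-week centered window ≈ one generation; 10/20-week windows
  supported). Edge weeks are missing; a zero-mean window yields a missing
  value with a warning, never infinity.
* **Detrending**: residuals from a lowess fit (default span 0.3) of count
  on week, recentered and shifted by the grand mean, so a CV of the
  detrended series keeps the original level as denominator. The span is a
  package default — smooth on the generation scale without absorbing weekly
  fluctuation; the weeks-60–80 analysis detrends the 21-week window per
  tube.
* **Stratified bootstrap**: whole replicate tubes are resampled with
  replacement within a treatment (tubes are the repeated-measures unit;
  keeping weeks intact preserves autocorrelation). Statistics are computed
  on the weeks pooled across resampled tubes. Intervals are BCa (bias
  correction from the bootstrap distribution, acceleration from a
  leave-one-tube-out jackknife); B = 10,000 by default, 2,000 in tests and
  the acceptance script. BCa at ~30 clusters is known to run 1–2 points
  below nominal 95 % coverage; the coverage test accounts for Monte-Carlo
  error accordingly. Whether the original analysis bootstrapped weeks,
  tubes or both is not recorded; cluster resampling of tubes is this
  package's documented choice.
* **Harvest contrast**: the harvested-minus-control difference in pooled
  window CV, with a percentile CI from resampling tubes independently in
  both groups — a sharper significance test than checking whether one
  treatment's mean falls outside the other's CI.
* **Yield**: cumulative adults removed over the harvest window (mean ± 2 SE
  across tubes) and the temporal CV of weekly takes (per-tube CV averaged,
  ± 2 SE).
* **CV trends**: per treatment, the pooled (week, rolling-CV) points are
  fitted with an anchored regression spline for each candidate df in
  {1…10, 15, 20}; the df with minimum Gaussian AIC is kept and the curve is
  reported ± 1 SE. The basis is a *nested* truncated-power cubic family
  (df = 1 is exactly an OLS line; each df adds one knot from a fixed
  coarse-to-fine sequence), so RSS is non-increasing in df. The anchor
  (average CV at the first defined week) is imposed exactly by shifting the
  response and using a basis that vanishes at that week. Note AIC treats
  the pooled points as independent; with overlapping rolling windows they
  are strongly autocorrelated, so chosen df tends toward the flexible end
  on long pooled series — the original analysis selected a representative
  6 df by model simplification, a step AIC alone does not reproduce.
* **Environment-code regressions**: OLS of a per-tube window statistic on
  the code var = 0 (constant), 1 (random), 2 (periodic). CVs and abundances
  are fitted on the natural-log scale by default: the experiment's reported
  CV intercepts (−1.45 … −1.90) are negative while CVs are positive, which
  only a log-scale response produces; a linear-scale option is retained.
  One-way ANOVA by environment is reported both with the code treated
  numerically (1 df, identical to the regression F) and categorically
  (2 df), since the experiment's printed df (1, 15) implies a numeric
  treatment with df lost to unreported filtering.
* **Size structure**: body lengths are log-transformed and smoothed with a
  Gaussian KDE (Silverman's rule bandwidth) evaluated on an 8192-point grid
  — 8192 read as the density grid size, the standard meaning of that
  argument — with a pointwise 95 % envelope from R = 10,000 resamples of
  individuals (resampling tubes instead is the undocumented alternative).
  The KDE is computed by linear binning + FFT convolution (the same scheme
  R's `density` uses); a direct-evaluation KDE agrees to numerical
  precision and serves as the test oracle. The grid extends 4 bandwidths
  beyond the data, so the density integrates to 1 within 10⁻³.

## Numerical and design notes

* All randomness flows through `numpy.random.Generator`; experiment-level
  streams are spawned from a single master seed via `SeedSequence`, so any
  collection is reproducible from one integer.
* Week ranges are inclusive everywhere ("weeks 60–80" = 21 censuses).
* A bootstrap resample on which a statistic is undefined (e.g. all-zero
  window) is redrawn and logged; degenerate inputs give degenerate CIs, not
  errors.
* `schedule_cv` requires ≥ 2 complete weeks and a nonzero mean; yields
  require at least one nonzero take.
* Problem sizes in the shipped tests and `scripts/acceptance.py` (B = 2,000
  bootstrap replicates, 500-trial coverage experiments, 20 calibration
  replicates) are chosen so the whole suite runs in well under a minute of
  simulation time while leaving Monte-Carlo error small relative to the
  tolerances tested.

## Known limitations

* The simulator is a stand-in with invented vital-rate forms; only the
  calibration targets above and the qualitative harvest × environment
  interaction are claimed.
* The threshold treatment's late-window CV in the simulator is not reliably
  below the proportional treatment's, unlike the experiment's report; the
  escapement sawtooth against a 173-adult limit interacts with the model's
  fast adult turnover.
* Replication of the experiment's printed tables requires its deposited
  census/size data (DRYAD doi:10.5061/dryad.bq135). The ingestion path
  (`read_census` with a column mapping) and the full window analysis
  (`replication.replicate_analysis`) are implemented and tested on
  simulated data; the numeric comparison against the printed coefficients
  is documented but unexercised without the download.
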