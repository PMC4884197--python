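"""Stochastic stage-structured microcosm simulator.

A daily-timestep egg → juvenile → adult model of a soil-mite population in a
closed tube fed on yeast balls. Density dependence acts through food: each
day's delivery tops up a decaying food pool, juveniles and adults consume it
up to their demand, and the realized intake ratio

    r = min(1, available / (demand_J * J + demand_A * A))

scales maturation, food-dependent survival and fecundity. Reduced density
therefore raises per-capita intake and triggers compensatory (and, through
the juvenile pipeline, potentially over-compensatory) recruitment — the
mechanism by which stage-selective harvesting interacts with a variable food
supply.

Demographic transitions are sampled (binomial survival/transition, Poisson
births); an *expectation mode* replaces every draw by its mean on a
real-valued state, which makes stage-flow conservation exact and gives the
deterministic equilibrium used for calibration. A lognormal daily
environmental multiplier on the effective intake ratio supplies process
noise beyond demographic sampling.

Default vital rates are calibrated so that an unharvested population on
constant food (2 balls/day) settles near the experiment's long-run stage
abundances (eggs ~560, juveniles ~1145, adults ~264) with an egg-to-first-
reproduction time of roughly 33 days; see docs/methods.md for the
calibration procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .census_io import CensusSeries
from .regimes import (FoodSchedule, HarvestRule, NO_HARVEST, PROPORTIONAL_40,
                      RandomRegimeSpec, THRESHOLD_173, harvest_take,
                      make_constant, make_periodic, make_random)

__all__ = [
    "PopulationState", "VitalRates", "ExperimentDesign", "DEFAULT_TREATMENTS",
    "init_state", "step_day", "step_day_components", "weekly_census_and_harvest",
    "run_replicate", "run_experiment", "experiment_schedules",
    "equilibrium_state", "generation_time",
]


@dataclass(frozen=True)
class PopulationState:
    """Stage abundances plus the standing food pool (balls). Counts are
    integers in sampling mode and reals in expectation mode."""

    eggs: float = 0
    juveniles: float = 0
    adults: float = 0
    food_pool: float = 0.0
    day: int = 0
    #: current log environmental multiplier (AR(1) process noise state)
    env_log: float = 0.0

    def __post_init__(self):
        if min(self.eggs, self.juveniles, self.adults) < 0 or self.food_pool < 0:
            raise ValueError("state counts and food pool must be non-negative")


@dataclass(frozen=True)
class VitalRates:
    """Daily vital rates and their food dependence.

    Food-dependent rates increase with the intake ratio r in [0, 1] and
    saturate because r itself saturates at full intake: survival runs
    linearly from its base to base + slope, per-female fecundity is
    ``max_fecundity * r`` (starvation shuts off reproduction), and juvenile
    maturation runs from ``maturation_min`` to ``maturation_max`` with gain
    ``r ** maturation_exponent`` — the default exponent of 2 makes
    maturation a convex, surplus-food response, mimicking famine-arrested
    cohorts that mature in bursts when food returns. Demands are in balls
    per individual per day; ``food_decay`` is the daily fraction of the
    leftover pool that spoils.

    Process noise beyond demographic sampling: a persistent AR(1) lognormal
    multiplier on fecundity (``env_noise_sd``, ``env_noise_rho``), an iid
    daily shock on adult survival (``adult_surv_noise_sd``), and a static
    per-tube lognormal fecundity multiplier (``tube_effect_sd``) giving
    replicate heterogeneity. All three are disabled in expectation mode.
    """

    egg_hatch_prob: float = 0.0840575
    egg_survival: float = 0.90
    juvenile_demand: float = 0.00199626
    adult_demand: float = 0.01298701
    maturation_min: float = 0.0
    maturation_max: float = 0.11560931
    juvenile_surv_base: float = 0.95142406
    juvenile_surv_slope: float = 0.0726
    adult_surv_base: float = 0.914625
    adult_surv_slope: float = 0.0725
    maturation_exponent: float = 2.0
    max_fecundity: float = 2.12911255
    female_fraction: float = 0.5
    food_decay: float = 0.4
    env_noise_sd: float = 0.5
    env_noise_rho: float = 0.9
    #: SD of an iid daily additive shock to adult survival probability
    adult_surv_noise_sd: float = 0.03
    #: SD of a static lognormal per-tube multiplier on max fecundity
    #: (replicate heterogeneity: micro-climate, founder composition)
    tube_effect_sd: float = 0.2

    def __post_init__(self):
        for name in ("egg_hatch_prob", "egg_survival", "maturation_min", "maturation_max",
                     "juvenile_surv_base", "adult_surv_base", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.juvenile_demand <= 0 or self.adult_demand <= 0:
            raise ValueError("demands must be positive")
        if self.max_fecundity < 0:
            raise ValueError("max_fecundity must be non-negative")

    # -- food-dependent rates -------------------------------------------------
    def maturation(self, r: float) -> float:
        gain = r ** self.maturation_exponent
        return self.maturation_min + (self.maturation_max - self.maturation_min) * gain

    def juvenile_survival(self, r: float) -> float:
        return min(0.999, self.juvenile_surv_base + self.juvenile_surv_slope * r)

    def adult_survival(self, r: float) -> float:
        return min(0.999, self.adult_surv_base + self.adult_surv_slope * r)

    def fecundity(self, r: float) -> float:
        return self.max_fecundity * r


DEFAULT_TREATMENTS: tuple[tuple[str, str], ...] = (
    ("constant", "none"), ("constant", "proportional"),
    ("random", "none"), ("random", "proportional"), ("random", "threshold"),
    ("periodic", "none"), ("periodic", "proportional"),
)

_HARVEST_RULES = {"none": NO_HARVEST, "proportional": PROPORTIONAL_40,
                  "threshold": THRESHOLD_173}


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the 42-tube experiment: 7 regime x harvest treatments with 6
    replicate tubes each, 102 weekly censuses, tubes inoculated with 300
    adults (150 of each sex) and 1000 juveniles."""

    n_replicates: int = 6
    treatments: tuple[tuple[str, str], ...] = DEFAULT_TREATMENTS
    n_weeks: int = 102
    initial_adults: int = 300
    initial_juveniles: int = 1000
    initial_eggs: int = 0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1 or self.n_weeks < 1:
            raise ValueError("replicates and weeks must be at least 1")
        for env, harv in self.treatments:
            if harv not in _HARVEST_RULES:
                raise ValueError(f"unknown harvest treatment {harv!r}")

    @property
    def n_tubes(self) -> int:
        return self.n_replicates * len(self.treatments)


def init_state(design: ExperimentDesign) -> PopulationState:
    """Inoculation state: adults + juveniles, no eggs, empty food pool."""
    return PopulationState(eggs=design.initial_eggs, juveniles=design.initial_juveniles,
                           adults=design.initial_adults, food_pool=0.0, day=0)


def step_day_components(state: PopulationState, food_delivered: float, rates: VitalRates,
                        rng: np.random.Generator | None = None,
                        expectation: bool = False) -> tuple[PopulationState, dict]:
    """Advance one day and return (new state, stage-flow components).

    The components dict records every flow (survivors, hatched, matured,
    births, deaths per stage, intake ratio) so conservation identities can be
    asserted exactly in expectation mode.
    """
    if not expectation and rng is None:
        raise ValueError("sampling mode needs an rng; pass expectation=True otherwise")

    available = state.food_pool + food_delivered
    demand = rates.juvenile_demand * state.juveniles + rates.adult_demand * state.adults
    r = 1.0 if demand == 0 else min(1.0, available / demand)
    consumed = min(available, demand)
    leftover = (available - consumed) * (1.0 - rates.food_decay)

    # environmental (process) noise: persistent (AR(1)) lognormal multiplier
    # on per-female fecundity, the rate most sensitive to ambient condition;
    # stationary SD of the log multiplier = env_noise_sd
    env_log = 0.0
    if not expectation and rates.env_noise_sd > 0:
        rho = rates.env_noise_rho
        innov_sd = rates.env_noise_sd * np.sqrt(1.0 - rho ** 2)
        env_log = rho * state.env_log + float(rng.normal(0.0, innov_sd))

    s_j = rates.juvenile_survival(r)
    s_a = rates.adult_survival(r)
    if not expectation and rates.adult_surv_noise_sd > 0:
        s_a = float(np.clip(s_a + rng.normal(0.0, rates.adult_surv_noise_sd), 0.5, 0.999))
    m = rates.maturation(r)
    fec = rates.fecundity(r) * float(np.exp(env_log))
    females = state.adults * rates.female_fraction

    if expectation:
        egg_surv = state.eggs * rates.egg_survival
        hatched = egg_surv * rates.egg_hatch_prob
        juv_surv = state.juveniles * s_j
        matured = juv_surv * m
        adult_surv = state.adults * s_a
        births = fec * females
    else:
        egg_surv = rng.binomial(int(state.eggs), rates.egg_survival)
        hatched = rng.binomial(egg_surv, rates.egg_hatch_prob)
        juv_surv = rng.binomial(int(state.juveniles), s_j)
        matured = rng.binomial(juv_surv, m)
        adult_surv = rng.binomial(int(state.adults), s_a)
        births = rng.poisson(fec * females)

    new = PopulationState(
        eggs=egg_surv - hatched + births,
        juveniles=juv_surv - matured + hatched,
        adults=adult_surv + matured,
        food_pool=leftover,
        day=state.day + 1,
        env_log=env_log,
    )
    components = {
        "intake_ratio": r, "env_multiplier": float(np.exp(env_log)), "consumed": consumed,
        "egg_deaths": state.eggs - egg_surv, "hatched": hatched, "births": births,
        "juvenile_deaths": state.juveniles - juv_surv, "matured": matured,
        "adult_deaths": state.adults - adult_surv,
    }
    return new, components


def step_day(state: PopulationState, food_delivered: float, rates: VitalRates,
             rng: np.random.Generator | None = None,
             expectation: bool = False) -> PopulationState:
    """Advance the population by one day (see :func:`step_day_components`)."""
    return step_day_components(state, food_delivered, rates, rng, expectation)[0]


def weekly_census_and_harvest(state: PopulationState, rule: HarvestRule,
                              week: int) -> tuple[dict, PopulationState]:
    """Morning census: record pre-harvest stage counts, then remove the take.

    Harvest happens after counting, so the recorded counts are pre-harvest
    and the recorded ``harvested`` is the number of adults brushed out.
    """
    adults = int(round(state.adults)) if isinstance(state.adults, float) else state.adults
    take = harvest_take(rule, adults, week)
    take = min(take, adults)
    record = {"week": week, "eggs": state.eggs, "juveniles": state.juveniles,
              "adults": state.adults, "harvested": take}
    return record, replace(state, adults=state.adults - take)


def run_replicate(design: ExperimentDesign, schedule: FoodSchedule, rule: HarvestRule,
                  rates: VitalRates, seed, tube: str = "tube_1",
                  harvest_label: str | None = None,
                  expectation: bool = False) -> CensusSeries:
    """Simulate one tube: daily dynamics with a weekly census-and-harvest.

    ``schedule`` must cover ``design.n_weeks * 7`` days. Deterministic under a
    fixed ``seed`` (ignored in expectation mode).
    """
    n_days = design.n_weeks * 7
    if len(schedule.days) < n_days:
        raise ValueError(f"schedule covers {len(schedule.days)} days, need {n_days}")
    rng = None if expectation else np.random.default_rng(seed)
    if not expectation and rates.tube_effect_sd > 0:
        # replicate heterogeneity: one static fecundity multiplier per tube
        mult = float(np.exp(rng.normal(0.0, rates.tube_effect_sd)))
        rates = replace(rates, max_fecundity=rates.max_fecundity * mult)
    state = init_state(design)
    records = []
    for day in range(1, n_days + 1):
        state = step_day(state, schedule.days[day - 1], rates, rng, expectation)
        if day % 7 == 0:
            week = day // 7
            record, state = weekly_census_and_harvest(state, rule, week)
            records.append(record)
    counts = pd.DataFrame.from_records(records)
    if not expectation:
        counts = counts.astype(int)
    label = harvest_label if harvest_label is not None else rule.kind
    return CensusSeries(tube=tube, environment=schedule.regime_label,
                        harvest=label, counts=counts)


def experiment_schedules(design: ExperimentDesign,
                         random_spec: RandomRegimeSpec | None = None) -> dict[str, FoodSchedule]:
    """One realized schedule per regime, shared by every tube in that regime
    (the food sequence is the environmental treatment, not a per-tube draw).
    The random regime's realization derives from ``design.master_seed``."""
    seed_seq = np.random.SeedSequence(design.master_seed).spawn(2)[0]
    n_days = design.n_weeks * 7
    rand_seed = int(seed_seq.generate_state(1)[0] % (2 ** 31))
    spec = random_spec or RandomRegimeSpec(seed=rand_seed)
    n_cycles = -(-n_days // 28)
    return {
        "constant": make_constant(n_days),
        "random": make_random(spec, n_days),
        "periodic": FoodSchedule(days=make_periodic(n_cycles).days[:n_days],
                                 regime_label="periodic"),
    }


def run_experiment(design: ExperimentDesign = ExperimentDesign(),
                   rates: VitalRates = VitalRates(),
                   random_spec: RandomRegimeSpec | None = None,
                   harvest_rules: dict[str, HarvestRule] | None = None) -> list[CensusSeries]:
    """Simulate the full experiment: every treatment x replicate tube.

    Per-tube RNG streams are spawned from ``design.master_seed``, so the whole
    collection is reproducible from a single integer.
    """
    rules = harvest_rules or _HARVEST_RULES
    root = np.random.SeedSequence(design.master_seed)
    _, tube_seq = root.spawn(2)
    schedules = experiment_schedules(design, random_spec)
    tube_seeds = tube_seq.spawn(design.n_tubes)
    out, i = [], 0
    for env, harv in design.treatments:
        for rep in range(1, design.n_replicates + 1):
            tube = f"{env[:4]}_{harv[:4]}_{rep:02d}"
            out.append(run_replicate(design, schedules[env], rules[harv],
                                     rates, tube_seeds[i], tube=tube,
                                     harvest_label=harv))
            i += 1
    return out


def equilibrium_state(rates: VitalRates = VitalRates(), n_days: int = 700,
                      daily_food: float = 2.0) -> tuple[PopulationState, float]:
    """Deterministic (expectation-mode) state after ``n_days`` on constant
    food, with the equilibrium intake ratio. Used for calibration checks."""
    design = ExperimentDesign(n_weeks=-(-n_days // 7))
    state = init_state(design)
    r = 1.0
    for _ in range(n_days):
        state, comp = step_day_components(state, daily_food, rates, expectation=True)
        r = comp["intake_ratio"]
    return state, r


def generation_time(rates: VitalRates = VitalRates(), daily_food: float = 2.0) -> float:
    """Mean egg-to-first-reproduction time (days) at the realized constant-food
    equilibrium intake ratio.

    Stage exits are geometric, so the mean conditional residence times are the
    reciprocals of the daily exit rates; reproduction starts the day after
    maturation.
    """
    _, r = equilibrium_state(rates, daily_food=daily_food)
    egg_exit = 1.0 - rates.egg_survival * (1.0 - rates.egg_hatch_prob)
    juv_exit = 1.0 - rates.juvenile_survival(r) * (1.0 - rates.maturation(r))
    return 1.0 / egg_exit + 1.0 / juv_exit + 1.0
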