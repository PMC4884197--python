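"""Food-supply regimes and adult-harvest rules.

The microcosm experiment feeds each population tube a daily ration of dried
yeast balls (1 ball = 0.0015 g) under one of three regimes with identical
long-run mean supply (2 balls/day):

* **constant** — two balls every day;
* **random** — daily counts drawn from a negative binomial (mean 2,
  dispersion 0.5), truncated to 0–13 balls/day, with each 56-day block
  constrained to the same total as the constant regime;
* **periodic** — a deterministic 28-day "seasonal" cycle: 9 days of no food,
  3 days of one ball, 2 of three, 9 of four, 3 of three and 2 of one.

Adults are harvested weekly during an active window (weeks 13–83 inclusive),
either *proportionally* (a fixed fraction of the adult census, 40 %/week) or
at a *threshold* / fixed-escapement rule (every adult above a fixed abundance,
173, is removed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import UndefinedStatisticError

#: grams of yeast per ball
BALL_GRAMS = 0.0015

#: the 28-day seasonal feeding cycle (balls/day); sums to 56 (mean 2/day)
PERIODIC_PATTERN: tuple[int, ...] = (0,) * 9 + (1,) * 3 + (3,) * 2 + (4,) * 9 + (3,) * 3 + (1,) * 2

REGIME_LABELS = ("constant", "random", "periodic")
HARVEST_KINDS = ("none", "proportional", "threshold")

#: default active harvest window, inclusive 1-based weeks
DEFAULT_HARVEST_WEEKS = (13, 83)


@dataclass(frozen=True)
class FoodSchedule:
    """A per-day ball-count sequence with its regime label."""

    days: tuple[int, ...]
    regime_label: str

    def __post_init__(self):
        if self.regime_label not in REGIME_LABELS:
            raise ValueError(f"unknown regime label {self.regime_label!r}")
        if any(d < 0 for d in self.days):
            raise ValueError("food schedule entries must be non-negative")
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))

    def __len__(self) -> int:
        return len(self.days)

    @property
    def total_balls(self) -> int:
        return sum(self.days)

    @property
    def total_grams(self) -> float:
        return self.total_balls * BALL_GRAMS


@dataclass(frozen=True)
class RandomRegimeSpec:
    """Parameters of the stochastic daily-supply regime.

    ``dispersion`` is the negative-binomial size parameter; small values give
    highly clumped supply. ``constrain_block_totals`` enforces equal total
    food per ``block_length``-day block across regimes (see
    :func:`make_random`).
    """

    mean: float = 2.0
    dispersion: float = 0.5
    daily_cap: int = 13
    block_length: int = 56
    seed: int = 0
    constrain_block_totals: bool = True

    def __post_init__(self):
        if self.mean <= 0 or self.dispersion <= 0:
            raise ValueError("mean and dispersion must be positive")
        if self.daily_cap < self.mean:
            raise ValueError("daily_cap must be at least the mean supply")
        if self.block_length < 1:
            raise ValueError("block_length must be positive")


@dataclass(frozen=True)
class PeriodicRegimeSpec:
    pattern: tuple[int, ...] = PERIODIC_PATTERN

    def __post_init__(self):
        if len(self.pattern) != 28 or sum(self.pattern) != 56:
            raise ValueError("periodic pattern must have 28 days summing to 56 balls")


@dataclass(frozen=True)
class HarvestRule:
    """Weekly adult-removal policy.

    kind
        ``none`` (control), ``proportional`` (remove ``rate`` of the adult
        census, rounded half-up to whole animals) or ``threshold`` (remove
        every adult above ``limit``; fixed escapement).
    active_weeks
        inclusive 1-based week range in which the rule applies.
    """

    kind: str = "none"
    rate: float = 0.0
    limit: int = 0
    active_weeks: tuple[int, int] = DEFAULT_HARVEST_WEEKS

    def __post_init__(self):
        if self.kind not in HARVEST_KINDS:
            raise ValueError(f"unknown harvest kind {self.kind!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")
        if self.limit < 0:
            raise ValueError("limit must be non-negative")
        if self.active_weeks[0] > self.active_weeks[1]:
            raise ValueError("active_weeks must be an inclusive (start, end) range")


#: the experiment's two harvest treatments and its control
PROPORTIONAL_40 = HarvestRule(kind="proportional", rate=0.40)
THRESHOLD_173 = HarvestRule(kind="threshold", limit=173)
NO_HARVEST = HarvestRule(kind="none")


def make_constant(n_days: int) -> FoodSchedule:
    """Constant regime: two balls every day."""
    if n_days < 0:
        raise ValueError("n_days must be non-negative")
    return FoodSchedule(days=(2,) * n_days, regime_label="constant")


def make_periodic(n_cycles: int, spec: PeriodicRegimeSpec | None = None) -> FoodSchedule:
    """Periodic regime: the 28-day seasonal pattern repeated ``n_cycles`` times."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    spec = spec or PeriodicRegimeSpec()
    return FoodSchedule(days=spec.pattern * n_cycles, regime_label="periodic")


def make_random(spec: RandomRegimeSpec, n_days: int) -> FoodSchedule:
    """Random regime: truncated negative-binomial daily supply.

    Draws NB(mean, dispersion) counts, truncates to ``[0, daily_cap]`` and —
    unless ``constrain_block_totals`` is off — nudges each ``block_length``-day
    block, one ball at a time between randomly chosen days, until it delivers
    exactly ``mean * block_length`` balls, so every regime supplies the same
    total food over a common horizon. Deterministic under ``spec.seed``.
    """
    if n_days < 0:
        raise ValueError("n_days must be non-negative")
    rng = np.random.default_rng(spec.seed)
    size = spec.dispersion
    p = size / (size + spec.mean)
    days = rng.negative_binomial(size, p, size=n_days)
    np.minimum(days, spec.daily_cap, out=days)

    if spec.constrain_block_totals:
        for start in range(0, n_days, spec.block_length):
            block = days[start:start + spec.block_length]
            target = round(spec.mean * len(block))
            while block.sum() != target:
                if block.sum() < target:
                    candidates = np.flatnonzero(block < spec.daily_cap)
                    block[rng.choice(candidates)] += 1
                else:
                    candidates = np.flatnonzero(block > 0)
                    block[rng.choice(candidates)] -= 1
    return FoodSchedule(days=tuple(int(d) for d in days), regime_label="random")


def weekly_totals(schedule: FoodSchedule | Sequence[int]) -> np.ndarray:
    """Consecutive non-overlapping 7-day sums; a trailing partial week is dropped."""
    days = np.asarray(schedule.days if isinstance(schedule, FoodSchedule) else schedule)
    n_weeks = len(days) // 7
    if n_weeks == 0:
        return np.array([], dtype=days.dtype if days.size else int)
    return days[: n_weeks * 7].reshape(n_weeks, 7).sum(axis=1)


def schedule_cv(schedule: FoodSchedule | Sequence[int]) -> float:
    """Coefficient of variation (sample SD / mean) of the weekly food totals."""
    totals = weekly_totals(schedule)
    if len(totals) < 2:
        raise UndefinedStatisticError("schedule CV needs at least two complete weeks")
    mean = totals.mean()
    if mean == 0:
        raise UndefinedStatisticError("schedule CV undefined for zero mean supply")
    return float(totals.std(ddof=1) / mean)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def harvest_take(rule: HarvestRule, adult_count: int, week: int) -> int:
    """Number of adults removed at the week's census under ``rule``.

    Zero outside the active window. Proportional: rate x count rounded
    half-up (whole animals). Threshold: everything above the limit. Never
    exceeds the census count.
    """
    if adult_count < 0:
        raise ValueError("adult_count must be non-negative")
    lo, hi = rule.active_weeks
    if rule.kind == "none" or not lo <= week <= hi:
        return 0
    if rule.kind == "proportional":
        return min(adult_count, _round_half_up(rule.rate * adult_count))
    return max(0, adult_count - rule.limit)
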