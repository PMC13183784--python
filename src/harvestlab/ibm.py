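"""Individual-based simulator of size-structured, iteroparous fish populations.

The simulator advances populations on a weekly clock.  Every week each live
fish is exposed, in fixed order, to natural mortality, somatic growth,
a maturation trial (if immature) and brood release (mature females).  On
harvest-cycle boundaries a size-selective removal operator is applied:

* ``positive``  — remove a proportion P of fish strictly above the length
  threshold;
* ``negative``  — remove P of fish at-or-below the threshold;
* ``random``    — remove P/2 of all fish irrespective of size.

With equal numbers above and below the threshold the two size-selective
regimes each remove P/2 of the whole population, which makes the three
regimes comparable at the population level.

State is stored column-wise in numpy arrays for speed; :class:`Individual`
is a per-fish view used by the object-level API and in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional

import numpy as np

from harvestlab._util import ConfigError, round_half_up

SEX_MALE = 0
SEX_FEMALE = 1

REGIMES = ("positive", "negative", "random")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class GrowthParams:
    """Biphasic growth plus the weight-length allometry.

    Weight grows by ``c * w**alpha`` per week before maturation and by
    ``c * w**alpha / (1 + r)`` after, ``r`` being the relative reproductive
    investment.  Length follows from ``w = exp(a_wl) * (L / 16)**b_wl``.
    """

    c: float = 0.08
    r: float = 0.6
    alpha: float = 0.75
    a_wl: float = math.log(0.1)  # log-weight of a 16 mm fish
    b_wl: float = 3.0
    ref_length_mm: float = 16.0

    def weight_from_length(self, length_mm):
        return np.exp(self.a_wl) * (np.asarray(length_mm) / self.ref_length_mm) ** self.b_wl

    def length_from_weight(self, weight_g):
        return self.ref_length_mm * (np.asarray(weight_g) / math.exp(self.a_wl)) ** (1.0 / self.b_wl)


@dataclass
class MaturationParams:
    lp50_mm: float = 16.0          # length at 50% weekly maturation probability
    slope: float = 1.2             # logit-scale slope per mm
    deterministic: bool = False    # mature at first crossing of lp50_mm instead


@dataclass
class FecundityParams:
    intercept: float = 2.0         # brood size at the length threshold
    length_slope: float = 0.5      # extra offspring per mm above threshold
    threshold_mm: float = 13.0     # below this females produce no offspring
    brood_interval_weeks: int = 6
    offspring_length_mm: float = 7.0
    offspring_length_sd: float = 0.4

    def brood_size(self, length_mm: float) -> int:
        if length_mm < self.threshold_mm:
            return 0
        return max(0, round_half_up(self.intercept + self.length_slope * (length_mm - self.threshold_mm)))


@dataclass
class SimConfig:
    """Full parameterisation of one simulated population."""

    regime: str = "positive"
    harvest_proportion: float = 0.40
    size_threshold_mm: float = 16.0
    cycle_weeks: int = 6
    census_fraction: float = 0.25
    n_initial: int = 140
    natural_mortality_week: float = 0.02
    growth: GrowthParams = field(default_factory=GrowthParams)
    maturation: MaturationParams = field(default_factory=MaturationParams)
    fecundity: FecundityParams = field(default_factory=FecundityParams)
    food_ration: float = 60.0               # grams of biomass fully fed per week
    growth_density_exponent: float = 1.0    # growth scales with min(1, ration/biomass)**e
    mortality_density_exponent: float = 0.0  # mu scales with max(1, biomass/ration)**e
    init_length_mean_mm: float = 13.0
    init_length_sd_mm: float = 3.0
    init_age_max_weeks: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigError("regime", f"must be one of {REGIMES}, got {self.regime!r}")
        if not 0.0 <= self.harvest_proportion <= 1.0:
            raise ConfigError("harvest_proportion", "must lie in [0, 1]")
        if self.cycle_weeks < 1:
            raise ConfigError("cycle_weeks", "must be >= 1")
        if not 0.0 < self.census_fraction <= 1.0:
            raise ConfigError("census_fraction", "must lie in (0, 1]")
        if self.n_initial < 0:
            raise ConfigError("n_initial", "must be non-negative")
        if self.natural_mortality_week < 0:
            raise ConfigError("natural_mortality_week", "must be non-negative")
        if self.size_threshold_mm <= 0:
            raise ConfigError("size_threshold_mm", "must be positive")
        if self.growth.c < 0 or self.growth.r < 0:
            raise ConfigError("growth_params", "c and r must be non-negative")
        if self.food_ration <= 0:
            raise ConfigError("food_ration", "must be positive")
        if self.fecundity.brood_interval_weeks < 1:
            raise ConfigError("fecundity_params", "brood_interval_weeks must be >= 1")


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    """One fish, as seen through the object-level API."""

    id: int
    sex: str
    age_weeks: float
    length_mm: float
    weight_g: float
    mature: bool
    alive: bool = True
    cohort_mark: Optional[str] = None
    gestating_weeks: float = 0.0


class PopulationState:
    """Column-wise store of the live fish in one population.

    Dead or harvested fish are logged by the caller and dropped from the
    arrays, so every row is a live individual.
    """

    __slots__ = ("week", "_next_id", "ids", "sex", "age", "length", "weight",
                 "mature", "cohort", "since_brood")

    def __init__(self) -> None:
        self.week: int = 0
        self._next_id: int = 0
        self.ids = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.int8)
        self.age = np.empty(0, dtype=np.float64)
        self.length = np.empty(0, dtype=np.float64)
        self.weight = np.empty(0, dtype=np.float64)
        self.mature = np.empty(0, dtype=bool)
        self.cohort = np.empty(0, dtype=object)   # cohort label or None
        self.since_brood = np.empty(0, dtype=np.float64)

    # -- bookkeeping ----------------------------------------------------

    @property
    def abundance(self) -> int:
        return int(self.ids.size)

    @property
    def biomass_g(self) -> float:
        return float(self.weight.sum())

    def add(self, sex, age, length, weight, mature) -> np.ndarray:
        """Append new fish; returns their ids."""
        n = len(sex)
        new_ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.ids = np.concatenate([self.ids, new_ids])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.age = np.concatenate([self.age, np.asarray(age, dtype=float)])
        self.length = np.concatenate([self.length, np.asarray(length, dtype=float)])
        self.weight = np.concatenate([self.weight, np.asarray(weight, dtype=float)])
        self.mature = np.concatenate([self.mature, np.asarray(mature, dtype=bool)])
        self.cohort = np.concatenate([self.cohort, np.full(n, None, dtype=object)])
        self.since_brood = np.concatenate([self.since_brood, np.zeros(n)])
        return new_ids

    def drop(self, mask: np.ndarray) -> None:
        """Remove fish where ``mask`` is True."""
        keep = ~mask
        for name in ("ids", "sex", "age", "length", "weight", "mature", "cohort", "since_brood"):
            setattr(self, name, getattr(self, name)[keep])

    def individuals(self) -> Iterator[Individual]:
        for i in range(self.abundance):
            yield Individual(
                id=int(self.ids[i]),
                sex="male" if self.sex[i] == SEX_MALE else "female",
                age_weeks=float(self.age[i]),
                length_mm=float(self.length[i]),
                weight_g=float(self.weight[i]),
                mature=bool(self.mature[i]),
                alive=True,
                cohort_mark=self.cohort[i],
                gestating_weeks=float(self.since_brood[i]),
            )


@dataclass
class CensusRecord:
    replicate: int
    regime: str
    week: int
    phase: str
    id: int
    sex: str
    length_mm: float
    mature: bool


@dataclass
class EventLog:
    """Everything observable about one simulated population."""

    censuses: list = field(default_factory=list)          # CensusRecord
    deaths: list = field(default_factory=list)            # (week, id, age, length, sex)
    harvests: list = field(default_factory=list)          # (week, regime, P, ids tuple)
    maturations: list = field(default_factory=list)       # (week, id, age, length)
    births: list = field(default_factory=list)            # (week, mother_id, mother_length, n)
    cohort_rows: list = field(default_factory=list)       # (cohort, cycle, week, dt, count, p_hs)
    abundance: list = field(default_factory=list)         # (week, abundance, biomass)

    @property
    def n_harvested(self) -> int:
        return sum(len(ids) for _, _, _, ids in self.harvests)

    @property
    def n_natural_deaths(self) -> int:
        return len(self.deaths)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def initialize_population(config: SimConfig, rng: Optional[np.random.Generator] = None) -> PopulationState:
    """Create the founding population.

    Sexes are split as evenly as parity allows; lengths are drawn from a
    truncated normal and ages uniformly on ``[0, init_age_max_weeks]``.
    Initial maturity follows the configured ogive at each fish's length.
    Deterministic given ``config.seed`` (or an explicit generator).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = PopulationState()
    n = config.n_initial
    if n == 0:
        return state
    n_males = n // 2
    sex = np.concatenate([np.full(n_males, SEX_MALE, dtype=np.int8),
                          np.full(n - n_males, SEX_FEMALE, dtype=np.int8)])
    rng.shuffle(sex)
    lo = config.fecundity.offspring_length_mm
    length = np.clip(rng.normal(config.init_length_mean_mm, config.init_length_sd_mm, n), lo, 28.0)
    age = rng.uniform(0.0, config.init_age_max_weeks, n)
    weight = config.growth.weight_from_length(length)
    mp = config.maturation
    if mp.deterministic:
        mature = length >= mp.lp50_mm
    else:
        p = 1.0 / (1.0 + np.exp(-mp.slope * (length - mp.lp50_mm)))
        mature = rng.uniform(size=n) < p
    state.add(sex, age, length, weight, mature)
    return state


def _density_factors(state: PopulationState, config: SimConfig) -> tuple[float, float]:
    """(growth multiplier <= 1, mortality multiplier >= 1) from current biomass."""
    biomass = state.biomass_g
    if biomass <= 0:
        return 1.0, 1.0
    intake = config.food_ration / biomass
    growth_f = min(1.0, intake) ** config.growth_density_exponent
    mort_f = max(1.0, 1.0 / intake) ** config.mortality_density_exponent
    return growth_f, mort_f


def step_week(state: PopulationState, config: SimConfig,
              rng: np.random.Generator, log: Optional[EventLog] = None) -> PopulationState:
    """Advance one week: natural mortality, growth, maturation, brood release.

    Mutates and returns ``state``.  All stochastic draws come from ``rng``.
    """
    state.week += 1
    week = state.week
    growth_f, mort_f = _density_factors(state, config)

    # natural mortality: per-capita survival e^(-mu) over one week
    mu = config.natural_mortality_week * mort_f
    if mu > 0 and state.abundance > 0:
        dead = rng.uniform(size=state.abundance) >= math.exp(-mu)
        if dead.any() and log is not None:
            for i in np.flatnonzero(dead):
                log.deaths.append((week, int(state.ids[i]), float(state.age[i]),
                                   float(state.length[i]),
                                   "male" if state.sex[i] == SEX_MALE else "female"))
        state.drop(dead)

    if state.abundance == 0:
        if log is not None:
            log.abundance.append((week, 0, 0.0))
        return state

    state.age += 1.0
    state.since_brood += 1.0

    # growth: biphasic weight increment, length via inverse allometry
    g = config.growth
    inc = g.c * state.weight ** g.alpha * growth_f
    inc = np.where(state.mature, inc / (1.0 + g.r), inc)
    state.weight = state.weight + inc
    state.length = np.maximum(state.length, g.length_from_weight(state.weight))

    # maturation trial for immature fish (monotone: never reverts)
    mp = config.maturation
    imm = ~state.mature
    if imm.any():
        if mp.deterministic:
            newly = imm & (state.length >= mp.lp50_mm)
        else:
            p = 1.0 / (1.0 + np.exp(-mp.slope * (state.length - mp.lp50_mm)))
            newly = imm & (rng.uniform(size=state.abundance) < p)
        if newly.any():
            if log is not None:
                for i in np.flatnonzero(newly):
                    log.maturations.append((week, int(state.ids[i]), float(state.age[i]),
                                            float(state.length[i])))
            state.mature |= newly
            state.since_brood[newly] = 0.0

    # brood release for due females
    fp = config.fecundity
    due = (state.sex == SEX_FEMALE) & state.mature & (state.since_brood >= fp.brood_interval_weeks)
    if due.any():
        mothers = np.flatnonzero(due)
        total = 0
        sexes, lengths = [], []
        for i in mothers:
            k = fp.brood_size(float(state.length[i]))
            if log is not None:
                log.births.append((week, int(state.ids[i]), float(state.length[i]), k))
            if k > 0:
                total += k
                sexes.append(rng.integers(0, 2, k).astype(np.int8))
                lengths.append(np.clip(
                    rng.normal(fp.offspring_length_mm, fp.offspring_length_sd, k),
                    1.0, None))
        state.since_brood[mothers] = 0.0
        if total > 0:
            sexes = np.concatenate(sexes)
            lengths = np.concatenate(lengths)
            weights = g.weight_from_length(lengths)
            state.add(sexes, np.zeros(total), lengths, weights, np.zeros(total, dtype=bool))

    if log is not None:
        log.abundance.append((week, state.abundance, state.biomass_g))
    return state


def apply_harvest(state: PopulationState, config: SimConfig,
                  rng: np.random.Generator, log: Optional[EventLog] = None,
                  p_override: Optional[float] = None,
                  regime_override: Optional[str] = None) -> list[Individual]:
    """Remove a size-selective random sample of fish; returns those removed.

    Called on cycle boundaries.  Counts use round-half-up of P times the
    number of eligible fish; the random regime removes P/2 of all fish.
    """
    P = config.harvest_proportion if p_override is None else p_override
    regime = config.regime if regime_override is None else regime_override
    if not 0.0 <= P <= 1.0:
        raise ConfigError("harvest_proportion", "must lie in [0, 1]")
    if regime not in REGIMES:
        raise ConfigError("regime", f"must be one of {REGIMES}, got {regime!r}")

    thr = config.size_threshold_mm
    if regime == "positive":
        eligible = np.flatnonzero(state.length > thr)
        k = round_half_up(P * eligible.size)
    elif regime == "negative":
        eligible = np.flatnonzero(state.length <= thr)
        k = round_half_up(P * eligible.size)
    else:
        eligible = np.arange(state.abundance)
        k = round_half_up(0.5 * P * eligible.size)
    k = min(k, eligible.size)
    if k == 0:
        if log is not None:
            log.harvests.append((state.week, regime, P, ()))
        return []
    take = rng.choice(eligible, size=k, replace=False)
    mask = np.zeros(state.abundance, dtype=bool)
    mask[take] = True
    removed = [Individual(
        id=int(state.ids[i]),
        sex="male" if state.sex[i] == SEX_MALE else "female",
        age_weeks=float(state.age[i]),
        length_mm=float(state.length[i]),
        weight_g=float(state.weight[i]),
        mature=bool(state.mature[i]),
        alive=False,
        cohort_mark=state.cohort[i],
    ) for i in take]
    if log is not None:
        log.harvests.append((state.week, regime, P, tuple(int(state.ids[i]) for i in take)))
    state.drop(mask)
    return removed


def census(state: PopulationState, config: SimConfig,
           rng: np.random.Generator, replicate: int = 0,
           phase: str = "", log: Optional[EventLog] = None) -> list[CensusRecord]:
    """Non-destructive simple random sample of round(fraction * N) live fish."""
    if not 0.0 < config.census_fraction <= 1.0:
        raise ConfigError("census_fraction", "must lie in (0, 1]")
    n = state.abundance
    if n == 0:
        return []
    k = min(round_half_up(config.census_fraction * n), n)
    idx = rng.choice(n, size=k, replace=False)
    records = [CensusRecord(
        replicate=replicate,
        regime=config.regime,
        week=state.week,
        phase=phase,
        id=int(state.ids[i]),
        sex="male" if state.sex[i] == SEX_MALE else "female",
        length_mm=float(state.length[i]),
        mature=bool(state.mature[i]),
    ) for i in idx]
    if log is not None:
        log.censuses.extend(records)
    return records


def mark_and_track_cohort(state: PopulationState, label: str,
                          selection: Callable[[Individual], bool] | np.ndarray,
                          log: Optional[EventLog] = None) -> "CohortTrack":
    """Tag matching live fish with ``label`` and open a cohort track.

    ``selection`` is either a predicate over :class:`Individual` or a boolean
    mask aligned with the state arrays.  The returned track holds the initial
    row (cycle 0, dt 0, marked count, P_hs 1); subsequent rows are appended by
    the caller each harvest cycle via :meth:`CohortTrack.append`.
    """
    from harvestlab.demography import CohortTrack

    if callable(selection):
        mask = np.fromiter((selection(ind) for ind in state.individuals()),
                           dtype=bool, count=state.abundance)
    else:
        mask = np.asarray(selection, dtype=bool)
    if mask.sum() == 0:
        raise ValueError(f"cohort {label!r}: selection matched no live fish")
    state.cohort[mask] = label
    track = CohortTrack(cohort=label)
    track.append(cycle=0, dt_weeks=0.0, count=float(mask.sum()), p_hs=1.0)
    if log is not None:
        log.cohort_rows.append((label, 0, state.week, 0.0, int(mask.sum()), 1.0))
    return track


def simulate_cohort_decay(n0: int, mu_week: float, p_hs: float, dt_weeks: float,
                          n_cycles: int, rng: np.random.Generator) -> "CohortTrack":
    """Stochastic marked-cohort decay: binomial natural survival then harvest.

    Each cycle the cohort first survives natural mortality with per-fish
    probability ``exp(-mu_week * dt_weeks)``, then harvest with probability
    ``p_hs``.  Recorded P_hs is the realized harvest survival (survivors /
    pre-harvest count), mirroring what a tracked experiment observes.
    """
    from harvestlab.demography import CohortTrack

    track = CohortTrack(cohort="sim")
    track.append(cycle=0, dt_weeks=0.0, count=float(n0), p_hs=1.0)
    n = n0
    p_nat = math.exp(-mu_week * dt_weeks)
    for c in range(1, n_cycles + 1):
        if n == 0:
            break
        survived = int(rng.binomial(n, p_nat))
        after = int(rng.binomial(survived, p_hs)) if survived > 0 else 0
        # a zero count ends the usable series, so its p_hs is never consumed;
        # clamp only to satisfy the (0, 1] contract
        realized = after / survived if survived > 0 else 1.0
        realized = max(realized, 1e-6)
        track.append(cycle=c, dt_weeks=dt_weeks, count=float(after), p_hs=realized)
        n = after
    return track
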