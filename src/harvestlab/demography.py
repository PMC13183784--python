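"""Mortality estimators, life-table generation time and elasticity analysis.

The mark-recapture estimator inverts the cohort decay model

    N_{t+1} = exp(-mu * dt) * P_hs * N_t

where ``mu`` is the instantaneous natural mortality rate (per week) and
``P_hs`` the harvest survival applied in that cycle.  After dividing out the
cumulative harvest survival, -log(adjusted count) is linear in elapsed weeks
with slope ``mu``; the pooled estimate is the least-squares slope (with
per-cohort intercepts when several cohorts are pooled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class CohortTrack:
    """Counts of one marked cohort across harvest cycles.

    Row ``k`` records the count measured at cycle boundary ``k`` (after that
    boundary's harvest), the elapsed weeks since the previous row, and the
    harvest survival P_hs applied at that boundary (1 for the marking row).
    """

    cohort: str
    cycles: list = field(default_factory=list)      # int
    dt_weeks: list = field(default_factory=list)    # float
    counts: list = field(default_factory=list)      # float
    p_hs: list = field(default_factory=list)        # float in (0, 1]

    def append(self, cycle: int, dt_weeks: float, count: float, p_hs: float) -> None:
        if not 0.0 < p_hs <= 1.0:
            raise ValueError(f"p_hs must lie in (0, 1], got {p_hs}")
        if count < 0:
            raise ValueError("counts must be non-negative")
        self.cycles.append(int(cycle))
        self.dt_weeks.append(float(dt_weeks))
        self.counts.append(float(count))
        self.p_hs.append(float(p_hs))

    def __len__(self) -> int:
        return len(self.counts)

    def adjusted_log_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(cumulative weeks, log count minus cumulative log harvest survival).

        The series is truncated at the first non-positive count.
        """
        counts = np.asarray(self.counts, dtype=float)
        n_usable = len(counts)
        nz = np.flatnonzero(counts <= 0)
        if nz.size:
            n_usable = int(nz[0])
        t = np.cumsum(np.asarray(self.dt_weeks[:n_usable], dtype=float))
        z = np.log(counts[:n_usable]) - np.cumsum(np.log(np.asarray(self.p_hs[:n_usable], dtype=float)))
        return t, z


@dataclass
class MortalityEstimate:
    mu_week: float
    ci: tuple[float, float]
    method: str                     # "observed" | "mark_recapture"
    n_intervals: int
    se: float = float("nan")

    def __post_init__(self) -> None:
        if self.mu_week < 0:
            raise ValueError("mu_week must be non-negative")
        lo, hi = self.ci
        if not (lo <= self.mu_week <= hi):
            raise ValueError("ci must contain the point estimate")


@dataclass
class LifeTable:
    """Ages ``x`` (in cycles), survivorship ``lx`` and fecundity ``mx``."""

    x: Sequence[float]
    lx: Sequence[float]
    mx: Sequence[float]

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        lx = np.asarray(self.lx, dtype=float)
        mx = np.asarray(self.mx, dtype=float)
        if not (len(x) == len(lx) == len(mx)):
            raise ValueError("x, lx, mx must have equal lengths")
        if lx.size == 0:
            raise ValueError("life table is empty")
        if not np.isclose(lx[0], 1.0):
            raise ValueError("l_0 must equal 1")
        if np.any(np.diff(lx) > 1e-12):
            raise ValueError("l_x must be non-increasing")
        if np.any(mx < 0):
            raise ValueError("m_x must be non-negative")


@dataclass
class ElasticityResult:
    elasticity: Optional[float]
    trait_change_rel: float
    biomass_change_rel: float
    transition: str = ""

    @property
    def defined(self) -> bool:
        return self.elasticity is not None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def observed_mortality(deaths_in_interval: int, abundance_at_start: int) -> float:
    """Directly observed mortality over one interval: deaths / starting abundance."""
    if abundance_at_start <= 0:
        raise ValueError("abundance_at_start must be positive")
    if deaths_in_interval < 0 or deaths_in_interval > abundance_at_start:
        raise ValueError("deaths must lie in [0, abundance_at_start]")
    return deaths_in_interval / abundance_at_start


def _pooled_slope(tracks: Iterable[CohortTrack]) -> tuple[float, int]:
    """Common least-squares slope of -z on t with per-track intercepts.

    Within-track demeaning makes this the fixed-effects (per-cohort
    intercept) estimator; it is exact on noiseless geometric decay.
    """
    ts, zs = [], []
    for tr in tracks:
        t, z = tr.adjusted_log_counts()
        if len(t) >= 2:
            ts.append(t - t.mean())
            zs.append(z - z.mean())
    if not ts:
        raise ValueError("need at least one track with >= 2 positive counts")
    t = np.concatenate(ts)
    z = np.concatenate(zs)
    denom = float(np.sum(t * t))
    if denom == 0:
        raise ValueError("no elapsed time in tracks")
    slope = float(np.sum(t * z)) / denom
    n_int = sum(len(ti) - 1 for ti in ts if len(ti) >= 2)
    return -slope, n_int


def _interval_increments(tracks: Iterable[CohortTrack]) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval (dt, -dz) pairs pooled over tracks."""
    dts, dzs = [], []
    for tr in tracks:
        t, z = tr.adjusted_log_counts()
        if len(t) >= 2:
            dts.append(np.diff(t))
            dzs.append(-np.diff(z))
    if not dts:
        raise ValueError("need at least one track with >= 2 positive counts")
    return np.concatenate(dts), np.concatenate(dzs)


def total_mortality_mark_recapture(track: CohortTrack | Sequence[CohortTrack],
                                   method: str = "regression",
                                   n_boot: int = 1000,
                                   seed: int = 0,
                                   ci_level: float = 0.95) -> MortalityEstimate:
    """Estimate instantaneous natural mortality (per week) from cohort decay.

    ``method`` is ``"regression"`` (least-squares slope of the adjusted
    log-counts, per-cohort intercepts) or ``"mean"`` (duration-weighted mean
    of single-interval estimates).  The CI is a percentile bootstrap over
    intervals.  A negative pooled estimate is floored at 0 with a warning.
    """
    tracks = [track] if isinstance(track, CohortTrack) else list(track)
    if method not in ("regression", "mean"):
        raise ValueError("method must be 'regression' or 'mean'")

    dts, dzs = _interval_increments(tracks)
    if method == "regression":
        mu_hat, n_int = _pooled_slope(tracks)
    else:
        mu_hat = float(np.sum(dzs)) / float(np.sum(dts))
        n_int = len(dts)

    # bootstrap: resample intervals, rebuild a decay series, re-take the slope
    rng = np.random.default_rng(seed)
    m = len(dts)
    idx = rng.integers(0, m, size=(n_boot, m))
    bt = np.cumsum(dts[idx], axis=1)
    bz = np.cumsum(dzs[idx], axis=1)
    bt = np.concatenate([np.zeros((n_boot, 1)), bt], axis=1)
    bz = np.concatenate([np.zeros((n_boot, 1)), bz], axis=1)
    tc = bt - bt.mean(axis=1, keepdims=True)
    zc = bz - bz.mean(axis=1, keepdims=True)
    slopes = np.sum(tc * zc, axis=1) / np.sum(tc * tc, axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(slopes, [alpha, 1.0 - alpha])
    se = float(np.std(slopes, ddof=1))

    if mu_hat < 0:
        warnings.warn("pooled natural mortality estimate was negative; floored at 0")
        mu_hat = 0.0
    lo = min(lo, mu_hat)
    hi = max(hi, mu_hat)
    return MortalityEstimate(mu_week=mu_hat, ci=(float(lo), float(hi)),
                             method="mark_recapture", n_intervals=n_int, se=se)


def single_interval_mortality(n_t: float, n_t1: float, p_hs: float, dt_weeks: float) -> float:
    """Closed-form mu = ln(P_hs * N_t / N_{t+1}) / dt for one interval."""
    if n_t <= 0 or n_t1 <= 0:
        raise ValueError("counts must be positive")
    if not 0.0 < p_hs <= 1.0:
        raise ValueError("p_hs must lie in (0, 1]")
    if dt_weeks <= 0:
        raise ValueError("dt_weeks must be positive")
    return float(np.log(p_hs * n_t / n_t1) / dt_weeks)


def generation_time(table: LifeTable, cycle_weeks: int) -> float:
    """Life-table generation time T = sum(x lx mx) / sum(lx mx), in days."""
    x = np.asarray(table.x, dtype=float)
    lx = np.asarray(table.lx, dtype=float)
    mx = np.asarray(table.mx, dtype=float)
    net = float(np.sum(lx * mx))
    if net <= 0:
        raise ValueError("zero net reproduction: sum(lx * mx) must be positive")
    t_cycles = float(np.sum(x * lx * mx)) / net
    return t_cycles * cycle_weeks * 7.0


def generations_per_year(generation_time_days: float, days_per_year: float = 365.25) -> float:
    """Number of generations per year implied by a generation time in days."""
    if generation_time_days <= 0:
        raise ValueError("generation_time_days must be positive")
    return days_per_year / generation_time_days


def elasticity(trait_before: float, trait_after: float,
               biomass_before: float, biomass_after: float,
               transition: str = "") -> ElasticityResult:
    """Proportional trait change per proportional biomass change.

    With no biomass change the elasticity is undefined and flagged rather
    than returned as a number.
    """
    if trait_before == 0:
        raise ValueError("trait_before must be non-zero")
    if biomass_before == 0:
        raise ValueError("biomass_before must be non-zero")
    d_trait = (trait_after - trait_before) / trait_before
    d_biomass = (biomass_after - biomass_before) / biomass_before
    if d_biomass == 0:
        return ElasticityResult(None, d_trait, 0.0, transition)
    return ElasticityResult(d_trait / d_biomass, d_trait, d_biomass, transition)


def population_harvest_fraction(P: float, regime: str, n_above: float, n_below: float) -> float:
    """Population-level removal fraction implied by a regime's eligibility rule.

    With equal numbers above and below the threshold, the positive and
    negative regimes each remove P/2 of the whole population; the random
    regime removes P/2 by construction.
    """
    if n_above < 0 or n_below < 0:
        raise ValueError("counts must be non-negative")
    total = n_above + n_below
    if total == 0:
        raise ValueError("counts must not both be zero")
    if regime == "positive":
        return P * n_above / total
    if regime == "negative":
        return P * n_below / total
    if regime == "random":
        return P / 2.0
    raise ValueError(f"unknown regime {regime!r}")
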