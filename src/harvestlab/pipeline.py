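"""End-to-end orchestration of multi-phase, multi-regime harvest experiments.

An :class:`ExperimentPlan` lays out ordered phases (baseline, harvest 1,
recovery, break, harvest 2 by default), each with its own duration, cycle
length, optional regime override and harvest-intensity multiplier.  The
default plan mirrors a decade-long design: 6-week harvest cycles during the
two harvest phases, 12-week random-harvest cycles in the recovery phase, a
harvest-free break, and a doubled-intensity 12-week tail at the end of the
second harvest phase.  Marked cohorts are opened at each cycle boundary of
the first harvest phase and followed until that phase ends.

Trait "evolution" in the generator is phenomenological: per-regime linear
drifts of the maturation midpoint, growth parameters and natural mortality
are applied weekly during drifting phases, so estimator pipelines can be
validated against known trajectories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from harvestlab import demography, growth, maturation, rates
from harvestlab._util import ConfigError
from harvestlab.demography import CohortTrack, LifeTable
from harvestlab.ibm import (
    EventLog,
    SimConfig,
    apply_harvest,
    census,
    initialize_population,
    mark_and_track_cohort,
    step_week,
)

REGIME_ORDER = ("positive", "negative", "random")


@dataclass
class PhaseSpec:
    label: str
    duration_weeks: int
    cycle_weeks: int
    harvest: bool = True
    regime_override: Optional[str] = None
    p_multiplier: float = 1.0
    mark_cohorts: bool = False
    apply_drift: bool = False

    def validate(self) -> None:
        if self.duration_weeks < 0:
            raise ConfigError("duration_weeks", f"phase {self.label!r}: must be non-negative")
        if self.cycle_weeks < 1:
            raise ConfigError("cycle_weeks", f"phase {self.label!r}: must be >= 1")
        if self.p_multiplier < 0:
            raise ConfigError("p_multiplier", f"phase {self.label!r}: must be non-negative")


@dataclass
class ExperimentPlan:
    phases: list[PhaseSpec]
    replicates: int = 3
    master_seed: int = 0
    cohort_mark_size: int = 40
    # per-regime weekly drifts of generator parameters, applied in drifting phases
    drifts: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates", "must be >= 1")
        for ph in self.phases:
            ph.validate()
            if ph.label == "recovery" and ph.harvest and ph.regime_override != "random":
                raise ConfigError("regime_override",
                                  "recovery phase must use the random regime for all populations")


def default_plan(master_seed: int = 0, replicates: int = 3,
                 scale: float = 1.0) -> ExperimentPlan:
    """The standard five-phase plan; ``scale`` shrinks durations for tests."""

    def d(weeks: int) -> int:
        return max(0, int(round(weeks * scale)))

    phases = [
        PhaseSpec("baseline", d(30), 6, harvest=False),
        PhaseSpec("harvest1", d(167), 6, harvest=True, mark_cohorts=True, apply_drift=True),
        PhaseSpec("recovery", d(154), 12, harvest=True, regime_override="random"),
        PhaseSpec("break", d(46), 12, harvest=False),
        PhaseSpec("harvest2", d(81), 6, harvest=True, apply_drift=True),
        PhaseSpec("harvest2", d(72), 12, harvest=True, p_multiplier=2.0, apply_drift=True),
    ]
    drifts = {
        "positive": {"lp50_mm": -0.010, "natural_mortality_week": 6e-5},
        "negative": {"lp50_mm": +0.004},
        "random": {"lp50_mm": -0.004},
    }
    return ExperimentPlan(phases=phases, replicates=replicates,
                          master_seed=master_seed, drifts=drifts)


def default_config() -> SimConfig:
    """SimConfig tuned so the default experiment is demographically regulated.

    Growth-mediated density dependence alone cannot stop mature fish from
    over-reproducing, so the default experiment also scales natural
    mortality with crowding; abundance then stays within a few hundred to
    ~1000 fish per population over the full plan.
    """
    from harvestlab.ibm import FecundityParams

    return SimConfig(
        natural_mortality_week=0.025,
        mortality_density_exponent=1.5,
        food_ration=40.0,
        fecundity=FecundityParams(intercept=1.2, length_slope=0.25),
    )


@dataclass
class PopulationRun:
    regime: str
    replicate: int
    log: EventLog
    tracks: list
    config: SimConfig


def _apply_drift(cfg: SimConfig, drift: dict) -> None:
    for key, delta in drift.items():
        if key == "lp50_mm":
            cfg.maturation.lp50_mm += delta
        elif key == "c":
            cfg.growth.c = max(1e-9, cfg.growth.c + delta)
        elif key == "r":
            cfg.growth.r = max(0.0, cfg.growth.r + delta)
        elif key == "natural_mortality_week":
            cfg.natural_mortality_week = max(0.0, cfg.natural_mortality_week + delta)
        else:
            raise ConfigError("drifts", f"unknown drift parameter {key!r}")


def _cohort_counts(state) -> dict:
    counts: dict = {}
    for label in state.cohort:
        if label is not None:
            counts[label] = counts.get(label, 0) + 1
    return counts


def run_population(plan: ExperimentPlan, base_config: SimConfig, regime: str,
                   replicate: int, rng: np.random.Generator) -> PopulationRun:
    """Simulate one population through every phase of the plan."""
    cfg = copy.deepcopy(base_config)
    cfg.regime = regime
    cfg.validate()
    drift = plan.drifts.get(regime, {})

    log = EventLog()
    state = initialize_population(cfg, rng)
    trackers: dict[str, CohortTrack] = {}
    tracks: list[CohortTrack] = []
    cohort_idx = 0
    cycle_count = 0

    for phase in plan.phases:
        regime_eff = phase.regime_override or regime
        for w in range(1, phase.duration_weeks + 1):
            step_week(state, cfg, rng, log)
            if phase.apply_drift and drift:
                _apply_drift(cfg, drift)
            if w % phase.cycle_weeks != 0:
                continue
            # --- cycle boundary ---
            cycle_count += 1
            pre = _cohort_counts(state)
            if phase.harvest:
                p_eff = min(1.0, cfg.harvest_proportion * phase.p_multiplier)
                apply_harvest(state, cfg, rng, log,
                              p_override=p_eff, regime_override=regime_eff)
            post = _cohort_counts(state)
            for label, track in trackers.items():
                n_pre = pre.get(label, 0)
                n_post = post.get(label, 0)
                p_hs = n_post / n_pre if (phase.harvest and n_pre > 0) else 1.0
                # rows with count 0 end the usable series, so their p_hs is
                # never consumed; clamp only to satisfy the (0, 1] contract
                p_hs = max(p_hs, 1e-6)
                track.append(cycle=cycle_count, dt_weeks=float(phase.cycle_weeks),
                             count=float(n_post), p_hs=min(p_hs, 1.0))
                log.cohort_rows.append((label, cycle_count, state.week,
                                        float(phase.cycle_weeks), n_post, min(p_hs, 1.0)))
            census(state, cfg, rng, replicate=replicate, phase=phase.label, log=log)
            if phase.mark_cohorts and state.abundance > 0:
                unmarked = np.array([c is None for c in state.cohort])
                n_pick = min(plan.cohort_mark_size, int(unmarked.sum()))
                if n_pick > 0:
                    idx = rng.choice(np.flatnonzero(unmarked), size=n_pick, replace=False)
                    mask = np.zeros(state.abundance, dtype=bool)
                    mask[idx] = True
                    label = f"{regime[:3]}{replicate}_c{cohort_idx:02d}"
                    track = mark_and_track_cohort(state, label, mask, log=None)
                    # rewrite the opening row with experiment-level indices
                    track.cycles[0] = cycle_count
                    log.cohort_rows.append((label, cycle_count, state.week, 0.0,
                                            int(track.counts[0]), 1.0))
                    trackers[label] = track
                    tracks.append(track)
                    cohort_idx += 1
        if phase.mark_cohorts:
            trackers.clear()   # cohorts are followed only within their phase

    return PopulationRun(regime=regime, replicate=replicate, log=log,
                         tracks=tracks, config=cfg)


def run_experiment(plan: ExperimentPlan, base_config: SimConfig) -> dict:
    """Run 3 regimes x ``plan.replicates`` populations; returns keyed runs.

    Child RNG streams are spawned deterministically from the master seed, so
    identical seeds give bit-identical event logs.
    """
    plan.validate()
    base_config.validate()
    n_pops = len(REGIME_ORDER) * plan.replicates
    seqs = np.random.SeedSequence(plan.master_seed).spawn(n_pops)
    runs = {}
    k = 0
    for regime in REGIME_ORDER:
        for rep in range(plan.replicates):
            rng = np.random.default_rng(seqs[k])
            runs[(regime, rep)] = run_population(plan, base_config, regime, rep, rng)
            k += 1
    return runs


# ---------------------------------------------------------------------------
# tidy frames
# ---------------------------------------------------------------------------


def frames_from_runs(runs: dict) -> dict[str, pd.DataFrame]:
    """Flatten event logs into tidy tables (census, deaths, harvests, ...)."""
    cen, dea, har, coh, abu, bir = [], [], [], [], [], []
    for (regime, rep), run in sorted(runs.items()):
        log = run.log
        for r in log.censuses:
            cen.append((rep, regime, r.week, r.phase, r.id, r.sex,
                        round(r.length_mm, 6), int(r.mature)))
        for (week, fid, age, length, sex) in log.deaths:
            dea.append((rep, regime, week, fid, round(age, 6), round(length, 6), sex))
        for (week, reg_eff, p, ids) in log.harvests:
            har.append((rep, regime, week, reg_eff, round(p, 6), len(ids),
                        ";".join(str(i) for i in ids)))
        for (label, cycle, week, dt, count, p_hs) in log.cohort_rows:
            coh.append((rep, regime, label, cycle, week, dt, count, round(p_hs, 9)))
        for (week, n, biomass) in log.abundance:
            abu.append((rep, regime, week, n, round(biomass, 6)))
        for (week, mid, mlen, n) in log.births:
            bir.append((rep, regime, week, mid, round(mlen, 6), n))
    return {
        "census": pd.DataFrame(cen, columns=["replicate", "regime", "week", "phase",
                                             "id", "sex", "length_mm", "mature"]),
        "deaths": pd.DataFrame(dea, columns=["replicate", "regime", "week", "id",
                                             "age_weeks", "length_mm", "sex"]),
        "harvests": pd.DataFrame(har, columns=["replicate", "regime", "week",
                                               "regime_applied", "p", "n_removed", "ids"]),
        "cohorts": pd.DataFrame(coh, columns=["replicate", "regime", "cohort", "cycle",
                                              "week", "dt_weeks", "count", "p_hs"]),
        "abundance": pd.DataFrame(abu, columns=["replicate", "regime", "week",
                                                "abundance", "biomass_g"]),
        "births": pd.DataFrame(bir, columns=["replicate", "regime", "week", "mother_id",
                                             "mother_length_mm", "brood_size"]),
    }


def tracks_from_frame(cohorts: pd.DataFrame) -> dict:
    """Rebuild CohortTrack objects per (regime, replicate) from the tidy table."""
    out: dict = {}
    for (rep, regime), sub in cohorts.groupby(["replicate", "regime"], sort=True):
        tracks = []
        for label, rows in sub.groupby("cohort", sort=True):
            rows = rows.sort_values("cycle")
            tr = CohortTrack(cohort=str(label))
            for _, r in rows.iterrows():
                tr.append(cycle=int(r["cycle"]), dt_weeks=float(r["dt_weeks"]),
                          count=float(r["count"]), p_hs=float(r["p_hs"]))
            tracks.append(tr)
        out[(regime, int(rep))] = tracks
    return out


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------

PHASE_ORDER = ["baseline", "harvest1", "recovery", "break", "harvest2"]

ALL_METRICS = ("length_above_threshold", "l50", "mortality_observed",
               "mortality_total", "generation_time", "fecundity",
               "haldanes", "elasticity")


def _agg(values: list[float]) -> tuple[float, float]:
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        return float("nan"), float("nan")
    se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else float("nan")
    return float(vals.mean()), float(se)


def _normalize(df: pd.DataFrame, value_col: str = "estimate") -> pd.DataFrame:
    """Add a column dividing each regime's estimates by its baseline value."""
    out = df.copy()
    out["normalized"] = np.nan
    for regime, sub in out.groupby("regime"):
        base = sub.loc[sub["phase"] == "baseline", value_col]
        if len(base) and np.isfinite(base.iloc[0]) and base.iloc[0] != 0:
            out.loc[sub.index, "normalized"] = sub[value_col] / base.iloc[0]
    return out


def _phase_windows(abundance: pd.DataFrame, census: pd.DataFrame) -> dict:
    """Week span of each phase per (regime, replicate), from census phases."""
    spans: dict = {}
    for (regime, rep, phase), sub in census.groupby(["regime", "replicate", "phase"]):
        spans[(regime, int(rep), phase)] = (int(sub["week"].min()), int(sub["week"].max()))
    return spans


def summarize(frames_or_runs, config: SimConfig,
              metrics: tuple[str, ...] = ALL_METRICS,
              seed: int = 0) -> dict[str, pd.DataFrame]:
    """Compute per-regime, per-phase report tables from simulation output.

    Accepts either the dict returned by :func:`run_experiment` or the tidy
    frames from :func:`frames_from_runs` (so re-summarizing stored CSVs gives
    the same report).  Metrics that lack data (e.g., no cohorts in a phase)
    come back as empty tables rather than failing the run.
    """
    if frames_or_runs and not isinstance(next(iter(frames_or_runs.keys()), None), str):
        frames = frames_from_runs(frames_or_runs)
    else:
        frames = frames_or_runs
    census = frames["census"]
    deaths = frames["deaths"]
    abundance = frames["abundance"]
    cohorts = frames["cohorts"]
    births = frames["births"]
    report: dict[str, pd.DataFrame] = {}
    if census.empty:
        return {m: pd.DataFrame() for m in metrics}

    phases = [p for p in PHASE_ORDER if p in set(census["phase"])]
    thr = config.size_threshold_mm

    # -- mean length above the size threshold -------------------------------
    if "length_above_threshold" in metrics:
        rows = []
        for regime, sub_r in census.groupby("regime"):
            for phase in phases:
                per_rep = []
                for rep, sub in sub_r[sub_r["phase"] == phase].groupby("replicate"):
                    big = sub.loc[sub["length_mm"] > thr, "length_mm"]
                    per_rep.append(big.mean() if len(big) else float("nan"))
                est, se = _agg(per_rep)
                rows.append((regime, phase, est, se, len(per_rep)))
        df = pd.DataFrame(rows, columns=["regime", "phase", "estimate", "se", "n_reps"])
        report["length_above_threshold"] = _normalize(df)

    # -- L50 from maturity ogives ------------------------------------------
    if "l50" in metrics:
        rows = []
        for regime, sub_r in census.groupby("regime"):
            for phase in phases:
                per_rep = []
                for rep, sub in sub_r[sub_r["phase"] == phase].groupby("replicate"):
                    try:
                        fit = maturation.fit_ogive(
                            lengths=sub["length_mm"].to_numpy(),
                            mature=sub["mature"].astype(bool).to_numpy())
                        per_rep.append(fit.l50_mm)
                    except ValueError:
                        per_rep.append(float("nan"))
                est, se = _agg(per_rep)
                rows.append((regime, phase, est, se, len(per_rep)))
        df = pd.DataFrame(rows, columns=["regime", "phase", "estimate", "se", "n_reps"])
        report["l50"] = _normalize(df)

    # -- directly observed natural mortality per 6-week interval ------------
    if "mortality_observed" in metrics:
        spans = _phase_windows(abundance, census)
        rows = []
        for regime in sorted(census["regime"].unique()):
            for phase in phases:
                per_rep = []
                for rep in sorted(census["replicate"].unique()):
                    key = (regime, int(rep), phase)
                    if key not in spans:
                        continue
                    w0, w1 = spans[key]
                    ab = abundance[(abundance["regime"] == regime)
                                   & (abundance["replicate"] == rep)].set_index("week")
                    de = deaths[(deaths["regime"] == regime) & (deaths["replicate"] == rep)]
                    vals = []
                    for start in range(w0, w1 - 5, 6):
                        if start not in ab.index:
                            continue
                        n0 = int(ab.loc[start, "abundance"])
                        if n0 <= 0:
                            continue
                        d = int(((de["week"] > start) & (de["week"] <= start + 6)).sum())
                        vals.append(demography.observed_mortality(min(d, n0), n0))
                    per_rep.append(float(np.mean(vals)) if vals else float("nan"))
                est, se = _agg(per_rep)
                rows.append((regime, phase, est, se, len(per_rep)))
        df = pd.DataFrame(rows, columns=["regime", "phase", "estimate", "se", "n_reps"])
        report["mortality_observed"] = _normalize(df)

    # -- total natural mortality from marked cohorts ------------------------
    mu_by_regime: dict[str, float] = {}
    if "mortality_total" in metrics or "generation_time" in metrics:
        rows = []
        track_map = tracks_from_frame(cohorts) if not cohorts.empty else {}
        for regime in sorted(census["regime"].unique()):
            per_rep = []
            for (reg, rep), tracks in track_map.items():
                if reg != regime:
                    continue
                try:
                    est = demography.total_mortality_mark_recapture(tracks, seed=seed)
                    per_rep.append(est.mu_week)
                except ValueError:
                    continue
            est, se = _agg(per_rep)
            mu_by_regime[regime] = est
            rows.append((regime, "harvest1", est, se, len(per_rep)))
        report["mortality_total"] = pd.DataFrame(
            rows, columns=["regime", "phase", "estimate", "se", "n_reps"])

    # -- life-table generation time -----------------------------------------
    gt_by_regime: dict[str, float] = {}
    if "generation_time" in metrics:
        rows = []
        track_map = tracks_from_frame(cohorts) if not cohorts.empty else {}
        for regime in sorted(census["regime"].unique()):
            tracks = [t for (reg, rep), ts in track_map.items() if reg == regime for t in ts]
            try:
                table = life_table_from_tracks(tracks, config)
                gt = demography.generation_time(table, config.cycle_weeks)
            except ValueError:
                gt = float("nan")
            gt_by_regime[regime] = gt
            rows.append((regime, "harvest1", gt, float("nan"), len(tracks)))
        report["generation_time"] = pd.DataFrame(
            rows, columns=["regime", "phase", "estimate", "se", "n_tracks"])

    # -- fecundity: mean brood size -----------------------------------------
    if "fecundity" in metrics:
        rows = []
        spans = _phase_windows(abundance, census)
        for regime in sorted(census["regime"].unique()):
            for phase in phases:
                per_rep = []
                for rep in sorted(census["replicate"].unique()):
                    key = (regime, int(rep), phase)
                    if key not in spans:
                        continue
                    w0, w1 = spans[key]
                    b = births[(births["regime"] == regime) & (births["replicate"] == rep)
                               & (births["week"] >= w0) & (births["week"] <= w1)]
                    pos = b.loc[b["brood_size"] > 0, "brood_size"]
                    per_rep.append(pos.mean() if len(pos) else float("nan"))
                est, se = _agg(per_rep)
                rows.append((regime, phase, est, se, len(per_rep)))
        df = pd.DataFrame(rows, columns=["regime", "phase", "estimate", "se", "n_reps"])
        report["fecundity"] = _normalize(df)

    # -- haldane rates of change in mature male length ----------------------
    if "haldanes" in metrics:
        rows = []
        for regime, sub_r in census.groupby("regime"):
            gt = gt_by_regime.get(regime, float("nan"))
            if not np.isfinite(gt) or gt <= 0:
                gt = 267.0   # equal-generation-time fallback
            for phase in [p for p in phases if p.startswith("harvest")]:
                sub = sub_r[(sub_r["phase"] == phase) & (sub_r["mature"] == 1)
                            & (sub_r["sex"] == "male")]
                if sub.empty:
                    continue
                weeks = np.sort(sub["week"].unique())
                if len(weeks) < 4:
                    continue
                third = max(1, len(weeks) // 3)
                early = sub[sub["week"].isin(weeks[:third])]["length_mm"].to_numpy()
                late = sub[sub["week"].isin(weeks[-third:])]["length_mm"].to_numpy()
                elapsed = float(np.mean(weeks[-third:]) - np.mean(weeks[:third]))
                if len(early) < 2 or len(late) < 2 or elapsed <= 0:
                    continue
                try:
                    est = rates.haldane_rate(early, late, elapsed, gt, seed=seed)
                except ValueError:
                    continue
                rows.append((regime, phase, est.h, est.s_p, est.g,
                             est.ci[0], est.ci[1], est.p_value))
        report["haldanes"] = pd.DataFrame(
            rows, columns=["regime", "phase", "h", "s_p", "g", "ci_lo", "ci_hi", "p"])

    # -- elasticities across phase transitions ------------------------------
    if "elasticity" in metrics:
        rows = []
        transitions = [("baseline", "harvest1"), ("recovery", "harvest2"),
                       ("baseline", "harvest2")]
        spans = _phase_windows(abundance, census)
        biomass_by = {}
        for regime in sorted(census["regime"].unique()):
            for phase in phases:
                vals = []
                for rep in sorted(census["replicate"].unique()):
                    key = (regime, int(rep), phase)
                    if key not in spans:
                        continue
                    w0, w1 = spans[key]
                    ab = abundance[(abundance["regime"] == regime)
                                   & (abundance["replicate"] == rep)
                                   & (abundance["week"] >= w0) & (abundance["week"] <= w1)]
                    if len(ab):
                        vals.append(ab["biomass_g"].mean())
                if vals:
                    biomass_by[(regime, phase)] = float(np.mean(vals))
        for trait in ("length_above_threshold", "l50", "mortality_observed"):
            if trait not in report:
                continue
            tdf = report[trait].set_index(["regime", "phase"])
            for regime in sorted(census["regime"].unique()):
                for (pa, pb) in transitions:
                    try:
                        t0 = float(tdf.loc[(regime, pa), "estimate"])
                        t1 = float(tdf.loc[(regime, pb), "estimate"])
                        b0 = biomass_by[(regime, pa)]
                        b1 = biomass_by[(regime, pb)]
                    except KeyError:
                        continue
                    if not (np.isfinite(t0) and np.isfinite(t1) and t0 != 0 and b0 != 0):
                        continue
                    res = demography.elasticity(t0, t1, b0, b1, transition=f"{pa}->{pb}")
                    rows.append((regime, trait, res.transition,
                                 res.elasticity if res.defined else float("nan"),
                                 res.trait_change_rel, res.biomass_change_rel))
        report["elasticity"] = pd.DataFrame(
            rows, columns=["regime", "trait", "transition", "elasticity",
                           "trait_change_rel", "biomass_change_rel"])

    return report


def life_table_from_tracks(tracks: list, config: SimConfig,
                           max_cycles: int = 24) -> LifeTable:
    """Build an (l_x, m_x) life table from cohort decay and the fecundity rule.

    Survivorship per cycle is the duration-weighted mean total survival
    (natural + harvest) across tracked cohort intervals; fecundity at age
    uses the forward growth map to get length-at-age and the configured
    linear brood-size rule, halved for the female fraction, gated on the
    maturation midpoint.
    """
    ratios, weights = [], []
    for tr in tracks:
        counts = np.asarray(tr.counts, dtype=float)
        dts = np.asarray(tr.dt_weeks, dtype=float)
        for k in range(1, len(counts)):
            if counts[k - 1] > 0 and dts[k] > 0:
                ratios.append((counts[k] / counts[k - 1]) ** (config.cycle_weeks / dts[k]))
                weights.append(counts[k - 1])
    if not ratios:
        raise ValueError("no usable cohort intervals for a life table")
    s_cycle = float(np.average(ratios, weights=weights))
    s_cycle = min(max(s_cycle, 1e-9), 1.0)

    g = config.growth
    fp = config.fecundity
    w0 = g.weight_from_length(fp.offspring_length_mm)
    ages_weeks = np.arange(0, max_cycles + 1) * config.cycle_weeks
    # maturation age for the forward map: first week the midpoint is crossed
    from harvestlab.growth import predict_biphasic
    probe = predict_biphasic(g.c, g.r, g.alpha, t_mature=1e9, w0=float(w0),
                             ages=np.arange(0, (max_cycles + 1) * config.cycle_weeks + 1))
    probe_len = g.length_from_weight(probe)
    crossing = np.flatnonzero(probe_len >= config.maturation.lp50_mm)
    t_mat = float(crossing[0]) if crossing.size else float("inf")
    wts = predict_biphasic(g.c, g.r, g.alpha, t_mature=t_mat, w0=float(w0),
                           ages=ages_weeks)
    lens = g.length_from_weight(wts)
    x = np.arange(0, max_cycles + 1, dtype=float)
    lx = s_cycle ** x
    mx = np.array([0.5 * fp.brood_size(float(L)) if (a * config.cycle_weeks) >= t_mat else 0.0
                   for a, L in zip(x, lens)])
    return LifeTable(x=x, lx=lx, mx=mx)
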